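"""Trial-archive layout shared by the CLI and the generators.

A dataset is a directory of dense per-trial arrays, ``trial_<k>.npy``, plus
a tab-separated label table ``labels.tsv`` with columns ``trial_id``,
``label`` and optionally ``group`` (source-epoch id for grouped CV) and any
extra metadata columns.  A small ``meta.json`` records the sampling rate
and event-relative start time for raw 2-D epochs, so synthetic data is a
drop-in dataset for the preprocessing chain.  EDF or other acquisition
formats are a documented extension point, not core: convert to this layout
first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tensorize import RecordingEpoch

__all__ = ["save_trials", "load_trials", "save_epochs", "load_epochs"]


def save_trials(path, trials, labels, groups=None) -> None:
    """Write stacked trial tensors + label table to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials = np.asarray(trials)
    table = {"trial_id": [], "label": list(np.asarray(labels))}
    for k, trial in enumerate(trials):
        name = f"trial_{k:05d}"
        np.save(path / f"{name}.npy", trial)
        table["trial_id"].append(name)
    if groups is not None:
        table["group"] = list(np.asarray(groups))
    pd.DataFrame(table).to_csv(path / "labels.tsv", sep="\t", index=False)


def load_trials(path):
    """Read a trial directory; returns ``(trials, labels, groups_or_None)``."""
    path = Path(path)
    table = pd.read_csv(path / "labels.tsv", sep="\t")
    trials = np.stack(
        [np.load(path / f"{tid}.npy") for tid in table["trial_id"]]
    )
    groups = table["group"].to_numpy() if "group" in table else None
    return trials, table["label"].to_numpy(), groups


def save_epochs(path, epochs, labels) -> None:
    """Write raw 2-D epochs with their rate/t0 metadata."""
    path = Path(path)
    rates = {e.rate for e in epochs}
    t0s = {e.t0 for e in epochs}
    if len(rates) != 1 or len(t0s) != 1:
        raise ValueError("all epochs of one archive must share rate and t0")
    save_trials(path, np.stack([e.samples for e in epochs]), labels)
    meta = {"rate": epochs[0].rate, "t0": epochs[0].t0}
    (path / "meta.json").write_text(json.dumps(meta))


def load_epochs(path):
    """Read raw epochs back as :class:`RecordingEpoch` objects + labels."""
    path = Path(path)
    trials, labels, _ = load_trials(path)
    meta = json.loads((path / "meta.json").read_text())
    epochs = [
        RecordingEpoch(samples=s, rate=meta["rate"], t0=meta["t0"])
        for s in trials
    ]
    return epochs, labels
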
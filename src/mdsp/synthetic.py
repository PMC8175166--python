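"""Seeded synthetic data: planted multilinear subspaces and MRCP-like EEG.

Two generators, both pure functions of their spec (seed included):

* :func:`planted_dataset` builds trial tensors whose class means differ only
  inside a known low-multilinear-rank subspace (random orthonormal bases
  ``Q_k`` shared across classes, distinct core tensors per class) plus iid
  Gaussian noise.  Because the noise is isotropic, the Fisher model is
  exactly correct and the planted bases are the ground truth the solver
  should recover — :func:`subspace_recovery_score` measures how well, in
  principal angles.

* :func:`mrcp_trials` emulates pre-movement EEG: a slow negative ramp
  (negativity-slope-like, starting ~0.4 s before the movement event and
  peaking at it) on a class-dependent, lateralized subset of channels,
  buried in 1/f ("pink") background noise on all channels.  It emulates
  the waveform's timing and lateralization only — no volume conduction,
  no artifacts, no inter-trial latency jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor_core import multi_mode_product
from .tensorize import RecordingEpoch

__all__ = [
    "PlantedSpec",
    "MrcpSpec",
    "planted_dataset",
    "subspace_recovery_score",
    "pink_noise",
    "mrcp_trials",
    "CHANNELS_1020",
]

# standard 19-electrode 10-20 montage ordering used by the MRCP generator
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclass
class PlantedSpec:
    """Planted-subspace tensor dataset parameters.

    shape : trial tensor shape (m_1, ..., m_h).
    ranks : per-mode planted ranks (r_1, ..., r_h), r_k <= m_k.
    n_classes : number of classes p (labels 1..p).
    trials_per_class : n_j, identical for every class.
    amplitude : effect size a >= 0 — the per-element RMS of each class-mean
        tensor (the planted structure is normalized before scaling), so
        ``noise_sd / amplitude`` is directly the element-level noise-to-
        signal ratio.
    noise_sd : iid Gaussian noise standard deviation sigma >= 0, same units
        as ``amplitude``.
    seed : RNG seed; identical specs give bitwise-identical datasets.
    """

    shape: tuple = (16, 50, 10)
    ranks: tuple = (2, 2, 2)
    n_classes: int = 2
    trials_per_class: int = 40
    amplitude: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(m) for m in self.shape)
        self.ranks = tuple(int(r) for r in self.ranks)
        if len(self.ranks) != len(self.shape):
            raise ValueError("ranks and shape must have equal length")
        if any(r < 1 or r > m for r, m in zip(self.ranks, self.shape)):
            raise ValueError(
                f"ranks {self.ranks} invalid for shape {self.shape}"
            )
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")


def planted_dataset(spec: PlantedSpec):
    """Generate a labeled tensor set with known discriminative subspaces.

    Returns ``(trials, labels, bases)``: trials stacked as
    (n, m_1, ..., m_h), integer labels 1..p, and the list of planted
    orthonormal bases ``Q_k`` (m_k x r_k) for recovery scoring.  The class-j
    mean tensor is a Gaussian core ``core_j`` lifted through the bases and
    rescaled to per-element RMS ``amplitude``; trials add iid
    N(0, noise_sd^2) noise.
    """
    rng = np.random.default_rng(spec.seed)
    bases = []
    for m, r in zip(spec.shape, spec.ranks):
        Q, _ = np.linalg.qr(rng.standard_normal((m, m)))
        bases.append(Q[:, :r])
    trials, labels = [], []
    for j in range(1, spec.n_classes + 1):
        core = rng.standard_normal(spec.ranks)
        structure = _expand(core, bases)
        rms = np.linalg.norm(structure) / np.sqrt(structure.size)
        mean = spec.amplitude * structure / rms
        noise = rng.standard_normal((spec.trials_per_class,) + spec.shape)
        trials.append(mean + spec.noise_sd * noise)
        labels.extend([j] * spec.trials_per_class)
    return np.concatenate(trials), np.asarray(labels), bases


def _expand(core: np.ndarray, bases) -> np.ndarray:
    """Lift an r_1 x ... x r_h core into the planted subspace:
    ``core x_1 Q_1^T ... x_h Q_h^T`` (each mode k contracted with the rows
    of Q_k^T, growing it from r_k to m_k)."""
    return multi_mode_product(core, [Q.T for Q in bases])


def subspace_recovery_score(estimated, truth):
    """Max principal angle (radians) per mode between estimated and
    planted column spans.

    Both matrix lists are orthonormalized by QR; the principal angles are
    the arccosines of the singular values of ``Q_true^T Q_est``.  0 means
    perfect recovery, pi/2 an orthogonal miss.  Each mode's score uses
    min(r_k, m_k') angles.
    """
    if len(estimated) != len(truth):
        raise ValueError("mode count mismatch between estimate and truth")
    angles = []
    for k, (U, Q) in enumerate(zip(estimated, truth), start=1):
        U = np.atleast_2d(np.asarray(U, dtype=float))
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        for name, A in (("estimated", U), ("truth", Q)):
            if np.linalg.matrix_rank(A) < A.shape[1]:
                raise ValueError(
                    f"{name} mode-{k} matrix is rank deficient"
                )
        Uo, _ = np.linalg.qr(U)
        Qo, _ = np.linalg.qr(Q)
        cos = np.clip(np.linalg.svd(Qo.T @ Uo, compute_uv=False).min(), -1, 1)
        if cos**2 > 0.5:
            # cosine loses half the digits near 0 angle; switch to the
            # sine of the angle via the orthogonal residual
            sin = np.linalg.svd(Uo - Qo @ (Qo.T @ Uo), compute_uv=False).max()
            angles.append(float(np.arcsin(np.clip(sin, 0.0, 1.0))))
        else:
            angles.append(float(np.arccos(cos)))
    return angles


def pink_noise(rng: np.random.Generator, shape: tuple,
               rate: float) -> np.ndarray:
    """1/f-power noise along the last axis, unit standard deviation."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = scale[1] if n > 1 else 1.0  # keep DC finite
    colored = np.fft.irfft(spectrum * scale, n=n, axis=-1)
    sd = colored.std()
    return colored / sd if sd > 0 else colored


@dataclass
class MrcpSpec:
    """MRCP-flavoured two-class EEG trial generator parameters.

    channels : electrode count (default 19, the 10-20 montage above).
    rate : sampling rate in Hz.
    duration : epoch length in seconds; epochs span [-duration, 0) relative
        to the movement event.
    active : per-class channel index sets carrying the pre-movement drift.
        Defaults lateralize contralaterally: class 1 ("left tap") loads
        right-hemisphere F4/C4/P4, class 2 ("right tap") loads F3/C3/P3.
    drift_amplitude : peak ramp value at the event, in arbitrary amplitude
        units; negative for the physiological negativity.
    drift_onset : seconds before the event at which the ramp starts
        (default 0.4 s, the negativity-slope component; the earlier
        readiness-potential component is not modelled separately).
    noise_sd : standard deviation of the 1/f background noise.
    trials_per_class, seed : sampling controls.
    """

    channels: int = 19
    rate: float = 100.0
    duration: float = 2.0
    active: tuple = ((5, 10, 15), (3, 8, 13))  # F4/C4/P4 vs F3/C3/P3
    drift_amplitude: float = -8.0
    drift_onset: float = 0.4
    noise_sd: float = 1.0
    trials_per_class: int = 40
    seed: int = 0

    def __post_init__(self):
        for s in self.active:
            if any(not 0 <= ch < self.channels for ch in s):
                raise ValueError(
                    f"active channel set {s} outside 0..{self.channels - 1}"
                )
        if not 0 < self.drift_onset <= self.duration:
            raise ValueError(
                f"drift onset {self.drift_onset}s outside epoch of "
                f"{self.duration}s"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def mrcp_trials(spec: MrcpSpec):
    """Generate labeled pre-movement epochs.

    Returns ``(epochs, labels)``: a list of :class:`RecordingEpoch` spanning
    [-duration, 0) seconds and integer labels (1..p, one per active set).
    Each trial is the class's linear ramp — zero before ``drift_onset``
    seconds pre-event, reaching ``drift_amplitude`` at the event — on its
    active channels, plus 1/f noise of sd ``noise_sd`` on every channel.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = round(spec.duration * spec.rate)
    t = -spec.duration + np.arange(n_t) / spec.rate  # [-duration, 0)
    ramp = np.clip((t + spec.drift_onset) / spec.drift_onset, 0.0, 1.0)
    ramp = spec.drift_amplitude * ramp
    epochs, labels = [], []
    for j, active in enumerate(spec.active, start=1):
        template = np.zeros((spec.channels, n_t))
        template[list(active)] = ramp
        for _ in range(spec.trials_per_class):
            noise = (
                spec.noise_sd * pink_noise(rng, (spec.channels, n_t), spec.rate)
                if spec.noise_sd > 0
                else 0.0
            )
            epochs.append(
                RecordingEpoch(samples=template + noise, rate=spec.rate,
                               t0=-spec.duration)
            )
            labels.append(j)
    return epochs, np.asarray(labels)
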
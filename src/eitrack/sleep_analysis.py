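"""Sleep-EEG preprocessing and stage-wise statistics.

Pipeline for overnight single-channel recordings scored in 30-s epochs:
band-pass filtering (0.6-20 Hz zero-phase FIR), selection of the
analysis window (20 min of pre-onset wake through the end of the first
REM episode), per-stage averaging of an E/I index, and the group
statistics used to compare stages: Kruskal-Wallis with the eta-squared
effect size, followed by Dunn's pairwise comparisons with Bonferroni
correction and Cramer's phi-squared effect sizes.

Hypnograms come from a two-column CSV (onset_s, stage) or EDF+
annotations; signals from CSV or EDF (via :mod:`mne`, if installed).
Stage vocabulary: Awake, S1, S2, S3/4, REM (stages 3 and 4 merged).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .ei_metrics import EISeries

__all__ = [
    "STAGES",
    "Hypnogram",
    "StageSummary",
    "bandpass",
    "analysis_window",
    "stage_average",
    "kruskal_wallis",
    "dunn_test",
    "read_edf_signal",
    "emd_artifact_hook",
]

logger = logging.getLogger(__name__)

STAGES = ("Awake", "S1", "S2", "S3/4", "REM")

# sleep-edfx annotation strings -> closed stage vocabulary
_EDFX_STAGE_MAP = {
    "Sleep stage W": "Awake",
    "Sleep stage 1": "S1",
    "Sleep stage 2": "S2",
    "Sleep stage 3": "S3/4",
    "Sleep stage 4": "S3/4",
    "Sleep stage R": "REM",
    "W": "Awake", "1": "S1", "2": "S2", "3": "S3/4", "4": "S3/4", "R": "REM",
    "Awake": "Awake", "S1": "S1", "S2": "S2", "S3/4": "S3/4", "REM": "REM",
}
_NREM = {"S1", "S2", "S3/4"}


def map_stage(label: str) -> str | None:
    """Map an annotation string to the stage vocabulary (None = drop)."""
    return _EDFX_STAGE_MAP.get(str(label).strip())


@dataclass
class Hypnogram:
    """Ordered, non-overlapping scored epochs (start_s, duration_s, stage)."""

    epochs: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        self.epochs = sorted(self.epochs, key=lambda e: e[0])
        t = -np.inf
        for start, dur, stage in self.epochs:
            if dur <= 0:
                raise ValueError("epoch durations must be positive")
            if start < t - 1e-9:
                raise ValueError("overlapping hypnogram epochs")
            if stage not in STAGES and stage != "other":
                raise ValueError(f"unknown stage label {stage!r}")
            t = start + dur

    @classmethod
    def from_csv(cls, path, epoch_s: float = 30.0) -> "Hypnogram":
        """Read (onset_s, stage) rows; each row spans to the next onset,
        the last row lasting one standard epoch."""
        df = pd.read_csv(path)
        onsets = df.iloc[:, 0].to_numpy(float)
        labels = df.iloc[:, 1].astype(str)
        epochs = []
        for i, (onset, label) in enumerate(zip(onsets, labels)):
            stage = map_stage(label)
            end = onsets[i + 1] if i + 1 < len(onsets) else onset + epoch_s
            if stage is not None:
                epochs.append((float(onset), float(end - onset), stage))
        return cls(epochs)

    @property
    def sleep_onset(self) -> float:
        """Start time of the first non-Awake epoch."""
        for start, _, stage in self.epochs:
            if stage in _NREM or stage == "REM":
                return start
        raise ValueError("hypnogram contains no sleep")

    def stage_at(self, t: float) -> str | None:
        for start, dur, stage in self.epochs:
            if start <= t < start + dur:
                return stage
        return None

    def first_rem_run(self) -> tuple[float, float]:
        """(start, end) of the first contiguous REM run after sleep onset."""
        start = end = None
        for s, d, stage in self.epochs:
            if stage == "REM":
                if start is None:
                    start = s
                    end = s + d
                elif np.isclose(s, end):
                    end = s + d
                else:
                    break
            elif start is not None:
                break
        if start is None:
            raise ValueError("hypnogram contains no REM episode")
        return start, end

    def has_interrupted_nrem(self) -> bool:
        """True if an Awake epoch occurs between sleep onset and the
        first REM episode (the exclusion rule for participants)."""
        onset = self.sleep_onset
        try:
            rem_start, _ = self.first_rem_run()
        except ValueError:
            return True
        for s, _, stage in self.epochs:
            if onset <= s < rem_start and stage == "Awake":
                return True
        return False


def analysis_window(hypnogram: Hypnogram, recording_start: float = 0.0) -> tuple[float, float]:
    """Analysis interval: 20 min before sleep onset (clamped to the
    recording start, labelled Awake) through the end of the first
    contiguous REM run.

    Raises ``ValueError`` when no REM episode exists (the recording is
    unusable for the NREM/REM comparison).
    """
    onset = hypnogram.sleep_onset
    _, rem_end = hypnogram.first_rem_run()
    return max(recording_start, onset - 1200.0), rem_end


def bandpass(
    eeg,
    fs: float = 100.0,
    lo: float = 0.6,
    hi: float = 20.0,
    numtaps: int = 6000,
) -> np.ndarray:
    """Zero-phase FIR band-pass filter (0.6-20 Hz defaults).

    A 6000-tap Hann-window FIR is applied forward and backward (net
    response |B(f)|^2, exactly zero-phase); edges use reflection
    padding.  The series must be longer than the filter.
    """
    x = np.asarray(eeg, dtype=float)
    if fs <= 2 * hi:
        raise ValueError("sampling rate too low for the requested passband")
    if x.size <= numtaps:
        raise ValueError("series shorter than the filter length")
    taps = signal.firwin(
        numtaps, [lo, hi], pass_zero=False, window="hann", fs=fs
    )
    pad = min(x.size - 1, numtaps)
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    fwd = signal.fftconvolve(xp, taps, mode="same")
    bwd = signal.fftconvolve(fwd[::-1], taps, mode="same")[::-1]
    return bwd[pad : pad + x.size]


@dataclass
class StageSummary:
    """Per-(participant, stage) time-averaged index values."""

    table: pd.DataFrame      # columns: participant, stage, value, n_samples

    def group(self, stage: str) -> np.ndarray:
        vals = self.table.loc[self.table["stage"] == stage, "value"].to_numpy()
        return vals[np.isfinite(vals)]

    def groups(self) -> dict[str, np.ndarray]:
        return {s: self.group(s) for s in STAGES if self.group(s).size}


def stage_average(
    index: EISeries,
    hypnogram: Hypnogram,
    window: tuple[float, float] | None = None,
    participant: str = "0",
) -> StageSummary:
    """Time-average an E/I index within each sleep stage.

    Samples are assigned the stage of the epoch containing them; times
    in the window but before sleep onset count as Awake (pre-onset
    wake).  Empty stages yield a NaN cell and a log entry.
    """
    if window is None:
        window = analysis_window(hypnogram)
    t_lo, t_hi = window
    t = np.asarray(index.t, float)
    vals = np.asarray(index.value, float)
    in_win = (t >= t_lo) & (t < t_hi)

    onset = hypnogram.sleep_onset
    stage_of = np.array(
        [
            "Awake" if ti < onset else (hypnogram.stage_at(ti) or "other")
            for ti in t[in_win]
        ]
    )
    rows = []
    for stage in STAGES:
        sel = vals[in_win][stage_of == stage]
        if sel.size == 0:
            logger.info("stage %s empty for participant %s", stage, participant)
            rows.append(dict(participant=participant, stage=stage,
                             value=np.nan, n_samples=0))
        else:
            rows.append(dict(participant=participant, stage=stage,
                             value=float(sel.mean()), n_samples=int(sel.size)))
    return StageSummary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# rank statistics

def _pooled_ranks(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    return np.split(ranks, splits), pooled, ranks


def kruskal_wallis(groups) -> tuple[float, float, float]:
    """Kruskal-Wallis H test with eta-squared effect size.

    Returns ``(H, p, eta_squared_H)`` where
    ``eta^2_H = (H - k + 1) / (n - k)`` for k groups and n total
    observations.  H uses the standard tie correction; if every pooled
    value is tied, H = 0 and p = 1.
    """
    rank_groups, pooled, ranks = _pooled_ranks(groups)
    n = pooled.size
    k = len(rank_groups)
    H = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / r.size for r in rank_groups
    ) - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie_corr == 0:                      # everything tied
        return 0.0, 1.0, 0.0
    H /= tie_corr
    p = float(stats.chi2.sf(H, df=k - 1))
    eta2 = (H - k + 1) / (n - k)
    return float(H), p, float(eta2)


def dunn_test(
    groups,
    labels=None,
    correction: str = "bonferroni",
    two_tailed: bool = True,
) -> pd.DataFrame:
    """Dunn's pairwise multiple-comparison test on pooled ranks.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((n(n+1)/12 - T) (1/n_i + 1/n_j))``
    with the tie term ``T = sum(t^3 - t) / (12 (n - 1))``.  p-values are
    two-tailed normal by default and Bonferroni-corrected over all
    k(k-1)/2 pairs.  The pairwise effect size is Cramer's
    ``phi^2 = z^2 / n_pair`` with ``n_pair = n_i + n_j``.
    """
    rank_groups, pooled, _ = _pooled_ranks(groups)
    k = len(rank_groups)
    n = pooled.size
    if labels is None:
        labels = [str(i) for i in range(k)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    n_pairs = k * (k - 1) // 2

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        ri, rj = rank_groups[i], rank_groups[j]
        se = np.sqrt(var_base * (1.0 / ri.size + 1.0 / rj.size))
        z = 0.0 if se == 0 else (ri.mean() - rj.mean()) / se
        p = 2.0 * stats.norm.sf(abs(z)) if two_tailed else stats.norm.sf(abs(z))
        if correction == "bonferroni":
            p_adj = min(1.0, p * n_pairs)
        elif correction in (None, "none"):
            p_adj = p
        else:
            raise ValueError(f"unknown correction {correction!r}")
        rows.append(dict(
            group_1=labels[i], group_2=labels[j], z=float(z),
            p=float(p), p_adj=float(p_adj),
            phi_squared=float(z**2 / (ri.size + rj.size)),
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O and hooks

def read_edf_signal(path, channel: str | None = None):
    """Read one channel from an EDF recording via :mod:`mne`.

    Returns ``(series, fs)``.  Raises ``ImportError`` with guidance if
    mne is not installed.
    """
    try:
        import mne
    except ImportError as exc:
        raise ImportError(
            "reading EDF files requires the optional dependency mne "
            "(pip install eitrack[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    name = channel or raw.ch_names[0]
    data = raw.get_data(picks=[name])[0]
    return np.asarray(data, float), float(raw.info["sfreq"])


def emd_artifact_hook(eeg, fs: float, method=None):
    """Optional artifact-removal hook applied before filtering.

    ``method`` is any callable ``(series, fs) -> series`` (e.g. an
    EMD-based cleaner); the default is a pass-through.
    """
    if method is None:
        return np.asarray(eeg, float)
    return np.asarray(method(eeg, fs), float)
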
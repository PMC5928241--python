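"""Intensity-to-beta preprocessing and quality control.

Converts methylated/unmethylated bead-type signal matrices to QC-filtered
beta-value matrices.  The processing order is fixed:

    quantile-normalize signals -> beta = M/(M+U) -> mask detection failures
    -> drop high-missingness probes -> drop low-quality samples

Beta values use the plain ratio M/(M+U) with no stabilizing offset.  A
``BetaMatrix`` is an ordinary pandas DataFrame (probes x samples) whose
missing mask is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import QCThresholds

__all__ = [
    "IntensityMatrix",
    "quantile_normalize_signals",
    "compute_beta",
    "mask_detection_failures",
    "filter_probes",
    "filter_samples",
    "mean_sample_methylation",
    "run_qc_pipeline",
]


@dataclass
class IntensityMatrix:
    """Methylated/unmethylated signals plus detection p-values, probes x samples."""

    M: pd.DataFrame
    U: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("U", self.U), ("detection_p", self.detection_p)):
            if not df.index.equals(self.M.index) or not df.columns.equals(self.M.columns):
                raise ValueError(f"{name} must share the probe and sample indices of M")
        if (self.M.to_numpy() < 0).any() or (self.U.to_numpy() < 0).any():
            raise ValueError("signal intensities must be non-negative")
        dp = self.detection_p.to_numpy()
        if ((dp < 0) | (dp > 1)).any():
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.M.index

    @property
    def samples(self) -> pd.Index:
        return self.M.columns

    def subset(self, probes=None, samples=None) -> "IntensityMatrix":
        probes = self.probes if probes is None else probes
        samples = self.samples if samples is None else samples
        return IntensityMatrix(
            M=self.M.loc[probes, samples].copy(),
            U=self.U.loc[probes, samples].copy(),
            detection_p=self.detection_p.loc[probes, samples].copy(),
        )


def quantile_normalize_signals(intensities: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize M and U signals together, per sample.

    For each sample the stacked vector of its M and U signals (length 2P)
    is mapped onto the across-sample mean of order statistics, so that
    after normalization every sample has the identical sorted stacked
    distribution.  Within-sample ranks are preserved; ties receive the
    reference value interpolated at their average rank.  The per-probe M/U
    pairing is preserved by unstacking back.
    """
    if intensities.M.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    n_probes = intensities.M.shape[0]
    stacked = np.vstack([intensities.M.to_numpy(float), intensities.U.to_numpy(float)])
    n = stacked.shape[0]
    reference = np.sort(stacked, axis=0).mean(axis=1)
    out = np.empty_like(stacked)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(stacked.shape[1]):
        ranks = rankdata(stacked[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    mk = lambda a: pd.DataFrame(a, index=intensities.M.index, columns=intensities.M.columns)
    return IntensityMatrix(
        M=mk(out[:n_probes]), U=mk(out[n_probes:]), detection_p=intensities.detection_p.copy()
    )


def compute_beta(intensities: IntensityMatrix) -> pd.DataFrame:
    """Beta values: beta = M / (M + U), elementwise; M + U = 0 yields missing."""
    M = intensities.M.to_numpy(float)
    U = intensities.U.to_numpy(float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("negative signal intensity")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / np.where(total > 0, total, 1.0), np.nan)
    return pd.DataFrame(beta, index=intensities.M.index, columns=intensities.M.columns)


def mask_detection_failures(
    beta: pd.DataFrame, detection_p: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Set data points with detection p-value > detection_alpha to missing."""
    thresholds = thresholds or QCThresholds()
    if beta.shape != detection_p.shape or not beta.index.equals(detection_p.index):
        raise ValueError("beta and detection_p must share shape and indices")
    return beta.mask(detection_p > thresholds.detection_alpha)


def filter_probes(
    beta: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, list]:
    """Drop probes missing in more than ``probe_missing_frac`` of samples.

    Returns the filtered matrix and the list of removed probe ids.  The
    boundary is strict: a probe missing in exactly 10% of samples is kept.
    """
    thresholds = thresholds or QCThresholds()
    missing_frac = beta.isna().mean(axis=1)
    removed = beta.index[missing_frac > thresholds.probe_missing_frac]
    return beta.drop(index=removed), list(removed)


@dataclass
class SampleQCReport:
    """Per-rule sample exclusion record."""

    call_rate: dict = field(default_factory=dict)
    average_intensity: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)  # sample -> list of failed rules
    call_rate_basis: str = "raw (pre-masking) detection p-values"

    def to_dict(self) -> dict:
        return {
            "call_rate": self.call_rate,
            "average_intensity": self.average_intensity,
            "excluded": self.excluded,
            "call_rate_basis": self.call_rate_basis,
        }


def filter_samples(
    intensities: IntensityMatrix,
    beta: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[pd.DataFrame, SampleQCReport]:
    """Drop samples failing any of the three sample-level QC rules.

    call rate  : fraction of probes with detection_p <= detection_alpha,
                 computed on the raw (pre-masking) detection table;
    intensity  : mean over probes of (M + U)/2 must be >= sample_min_intensity
                 AU and >= sample_median_frac of the experiment-wide median
                 of the per-sample average intensities.
    """
    thresholds = thresholds or QCThresholds()
    report = SampleQCReport()
    call_rate = (intensities.detection_p <= thresholds.detection_alpha).mean(axis=0)
    avg_intensity = ((intensities.M + intensities.U) / 2.0).mean(axis=0)
    experiment_median = float(avg_intensity.median())
    report.call_rate = {s: float(v) for s, v in call_rate.items()}
    report.average_intensity = {s: float(v) for s, v in avg_intensity.items()}

    for sample in beta.columns:
        reasons = []
        if call_rate[sample] < thresholds.sample_call_rate:
            reasons.append("call_rate")
        if avg_intensity[sample] < thresholds.sample_min_intensity:
            reasons.append("low_intensity")
        if avg_intensity[sample] < thresholds.sample_median_frac * experiment_median:
            reasons.append("below_median_fraction")
        if reasons:
            report.excluded[sample] = reasons

    keep = [s for s in beta.columns if s not in report.excluded]
    if not keep:
        raise ValueError(f"all samples excluded by QC: {report.excluded}")
    return beta[keep], report


def mean_sample_methylation(beta: pd.DataFrame) -> pd.Series:
    """Per-sample arithmetic mean beta over non-missing probes.

    A sample with no evaluable probes yields NaN.
    """
    return beta.mean(axis=0, skipna=True)


def run_qc_pipeline(
    intensities: IntensityMatrix, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full preprocessing chain; returns (beta matrix, QC report dict)."""
    thresholds = thresholds or QCThresholds()
    n_probes0, n_samples0 = intensities.M.shape
    normalized = quantile_normalize_signals(intensities)
    beta = compute_beta(normalized)
    beta = mask_detection_failures(beta, normalized.detection_p, thresholds)
    beta, removed_probes = filter_probes(beta, thresholds)
    # sample rules are evaluated on the raw, pre-normalization intensities
    raw_kept = intensities.subset(probes=beta.index)
    beta, sample_report = filter_samples(raw_kept, beta, thresholds)
    report = {
        "input": {"probes": n_probes0, "samples": n_samples0},
        "probes_removed": removed_probes,
        "n_probes_removed": len(removed_probes),
        "samples_removed": sample_report.excluded,
        "n_samples_removed": len(sample_report.excluded),
        "sample_qc": sample_report.to_dict(),
        "output": {"probes": int(beta.shape[0]), "samples": int(beta.shape[1])},
    }
    return beta, report
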
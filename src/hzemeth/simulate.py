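"""Synthetic methylation-array experiment generator.

Produces every input the analysis pipeline consumes, with full seed
control: sample sheets for a dose x time x replicate exposure design,
probe manifests on a synthetic chromosome with CpG-island / gene /
chromatin-state annotations, methylated/unmethylated intensity matrices
with planted dose effects and culture drift, tumor/normal beta matrices
with a planted discriminating signature, and read intervals with
configurable enrichment over target regions.

The synthetic chromosome is built from repeating 20-kb "gene units", each
carrying a CpG-island promoter gene.  Even units are '+'-stranded, odd
units '-'-stranded (mirrored layout), so both orientations of the
shore/gene-body logic are exercised.  Chromatin-state segments tile each
unit and are aligned with the layout (promoter states over islands,
enhancer states over shores, transcription states over gene bodies), so
baseline methylation, CGI context and chromatin context are coupled the
way they are on a real array.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import GenomeAnnotation
from .config import BaselineMixture, SimulationConfig
from .preprocess import IntensityMatrix

__all__ = [
    "generate_sample_sheet",
    "generate_probe_annotation",
    "generate_intensities",
    "generate_tumor_normal",
    "generate_read_intervals",
    "UNIT_LENGTH",
]

UNIT_LENGTH = 20_000
CHROM = "chrS"

# stream ids: one independent child generator per stage of the simulation
_STREAM_SHEET = 1
_STREAM_LAYOUT = 2
_STREAM_INTENSITIES = 3
_STREAM_TUMOR = 4
_STREAM_READS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def generate_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """One record per dose x time x replicate; chips filled to capacity.

    Samples are shuffled, then assigned to chips of ``chip_capacity``
    (default 12 = 6 rows x 2 columns); the row index (1-6) is the
    within-chip position // 2 + 1, so replicates land on randomized rows.
    """
    if not len(config.doses) or not len(config.time_points) or config.n_replicates < 1:
        raise ValueError("doses, time_points and n_replicates must be non-empty/positive")
    records = []
    for dose in config.doses:
        for time in config.time_points:
            for rep in range(1, config.n_replicates + 1):
                records.append({"dose": float(dose), "time": float(time), "replicate": rep})
    sheet = pd.DataFrame(records)
    sheet["sample_id"] = [
        f"{config.series}_d{r.dose:g}_t{r.time:g}_r{r.replicate}" for r in sheet.itertuples()
    ]
    rng = _rng(config.seed, _STREAM_SHEET)
    order = rng.permutation(len(sheet))
    position = np.empty(len(sheet), dtype=int)
    position[order] = np.arange(len(sheet))
    sheet["chip"] = [f"chip{p // config.chip_capacity + 1}" for p in position]
    sheet["row"] = [(p % config.chip_capacity) // 2 + 1 for p in position]
    sheet["series"] = config.series
    return sheet.set_index("sample_id")[["dose", "time", "replicate", "chip", "row", "series"]]


# ---------------------------------------------------------------------------
# probe manifest + genome annotation
# ---------------------------------------------------------------------------

DEFAULT_SHARES = {"Island": 0.25, "Shore": 0.25, "Body": 0.25, "Other": 0.25}

# per-unit region offsets, 0-based half-open, for '+' (even) units
_PLUS = {
    "island": (5000, 6000),
    "tss": 5500,
    "tes": 15000,
    "shore5": (3000, 5000),
    "shore3": (6000, 8000),
    "body": (8000, 15000),
    "other": (15200, 19500),
    "segments": [
        (0, 3000, 13),
        (3000, 5000, 4),
        (5000, 6000, 1),
        (6000, 8000, 6),
        (8000, 10500, 9),
        (10500, 13000, 10),
        (13000, 15000, 11),
        (15000, 17500, 12),
        (17500, 20000, 13),
    ],
}
# mirrored layout for '-' (odd) units
_MINUS = {
    "island": (14000, 15000),
    "tss": 14500,
    "tes": 5000,
    "shore5": (15000, 17000),
    "shore3": (12000, 14000),
    "body": (5000, 12000),
    "other": (500, 4500),
    "segments": [
        (0, 2500, 13),
        (2500, 5000, 12),
        (5000, 7000, 11),
        (7000, 9500, 10),
        (9500, 12000, 9),
        (12000, 14000, 7),
        (14000, 15000, 1),
        (15000, 17000, 5),
        (17000, 20000, 13),
    ],
}


def _allocate_counts(total: int, shares: dict) -> dict:
    """Largest-remainder apportionment of ``total`` by fractional shares."""
    keys = list(shares)
    exact = np.array([shares[k] * total for k in keys])
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts))


def generate_probe_annotation(
    config: SimulationConfig, shares: dict | None = None
) -> tuple[pd.DataFrame, GenomeAnnotation]:
    """Synthetic chromosome layout and a probe manifest placed on it.

    ``shares`` gives the fraction of probes per CGI category
    ({Island, Shore, Body, Other}, must sum to 1); each category's count is
    within +-1 of its exact share.  Returns (probes, annotation); probes has
    columns probe_id, chrom, pos (1-based), truth_category, chromatin_state
    (raw integer state).
    """
    if config.n_probes < 1:
        raise ValueError("n_probes must be positive")
    shares = dict(DEFAULT_SHARES if shares is None else shares)
    if set(shares) != {"Island", "Shore", "Body", "Other"}:
        raise ValueError("shares must have keys Island, Shore, Body, Other")
    if not np.isclose(sum(shares.values()), 1.0):
        raise ValueError("layout shares must sum to 1")

    rng = _rng(config.seed, _STREAM_LAYOUT)
    # enough units that every per-unit region can host its probes without
    # position collisions (island region is the narrowest at 1000 bp)
    n_units = max(4, int(np.ceil(config.n_probes / 500)))

    islands, genes, segments = [], [], []
    for u in range(n_units):
        base = u * UNIT_LENGTH
        lay = _PLUS if u % 2 == 0 else _MINUS
        strand = "+" if u % 2 == 0 else "-"
        islands.append((CHROM, base + lay["island"][0], base + lay["island"][1]))
        genes.append((CHROM, base + lay["tss"], base + lay["tes"], strand, f"gene_{u:05d}"))
        for s, e, state in lay["segments"]:
            segments.append((CHROM, base + s, base + e, state))
    annotation = GenomeAnnotation(
        cgi=pd.DataFrame(islands, columns=["chrom", "start", "end"]),
        genes=pd.DataFrame(genes, columns=["chrom", "tss", "tes", "strand", "gene_id"]),
        chromatin=pd.DataFrame(segments, columns=["chrom", "start", "end", "state"]),
    )

    counts = _allocate_counts(config.n_probes, shares)
    # shore probes split between the 5' and 3' sides
    region_counts = {
        "Island": counts["Island"],
        "Shore5": counts["Shore"] - counts["Shore"] // 2,
        "Shore3": counts["Shore"] // 2,
        "Body": counts["Body"],
        "Other": counts["Other"],
    }
    region_key = {
        "Island": "island",
        "Shore5": "shore5",
        "Shore3": "shore3",
        "Body": "body",
        "Other": "other",
    }
    positions, categories = [], []
    for category, n_cat in region_counts.items():
        per_unit = _allocate_counts(n_cat, {u: 1.0 / n_units for u in range(n_units)})
        for u, n_u in per_unit.items():
            if n_u == 0:
                continue
            lay = _PLUS if u % 2 == 0 else _MINUS
            lo, hi = lay[region_key[category]]
            offs = rng.choice(hi - lo, size=n_u, replace=False)
            for off in offs:
                positions.append(u * UNIT_LENGTH + lo + int(off))
                categories.append(category)

    order = np.argsort(positions, kind="stable")
    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(config.n_probes)],
            "chrom": CHROM,
            "pos": np.asarray(positions)[order] + 1,  # 1-based manifest coordinate
            "truth_category": np.asarray(categories)[order],
        }
    )
    seg_starts = annotation.chromatin["start"].to_numpy()
    seg_states = annotation.chromatin["state"].to_numpy()
    idx = np.searchsorted(seg_starts, probes["pos"].to_numpy() - 1, side="right") - 1
    probes["chromatin_state"] = seg_states[idx]
    # truth shore sides collapse to the printed category names
    probes["truth_category"] = probes["truth_category"].replace({"Body": "GeneBody"})
    return probes, annotation


# ---------------------------------------------------------------------------
# intensities with planted effects
# ---------------------------------------------------------------------------

#: chromatin states treated as "open" (promoter/enhancer) when coupling
#: fe-like dose effects to chromatin context
_OPEN_STATES = {1, 2, 3, 4, 5, 6, 7}


def _draw_baselines(probes: pd.DataFrame, mixture: BaselineMixture, rng) -> np.ndarray:
    """Baseline beta per probe, coupled to CGI category when known.

    Island probes draw mostly from the low-methylation mode, gene-body and
    intergenic probes mostly from the high mode, shores are mixed --
    reproducing the bimodal marginal with realistic context structure.
    """
    n = len(probes)
    low_prob = np.full(n, mixture.weights[0])
    if "truth_category" in probes.columns:
        cat = probes["truth_category"].to_numpy()
        low_prob = np.where(cat == "Island", 0.90, low_prob)
        low_prob = np.where((cat == "Shore5") | (cat == "Shore3"), 0.50, low_prob)
        low_prob = np.where((cat == "GeneBody") | (cat == "Other"), 0.15, low_prob)
    pick_low = rng.random(n) < low_prob
    means = np.where(pick_low, mixture.means[0], mixture.means[1])
    conc = np.where(pick_low, mixture.concentrations[0], mixture.concentrations[1])
    return rng.beta(means * conc, (1.0 - means) * conc)


def _select_effect_probes(
    config: SimulationConfig, probes: pd.DataFrame, baseline: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Choose dose-responsive, drift, and dual probes; return index arrays.

    Dose-probe selection follows the effect profile: fe-like targets
    low-baseline sites (preferring open-chromatin context when available),
    si-like targets intermediate-baseline sites, x-like high-baseline sites.
    """
    n = len(probes)
    profile = config.effect_profile
    if profile == "fe_like":
        weight = np.where(baseline < 0.35, 1.0, 1e-6)
        if "chromatin_state" in probes.columns:
            open_chrom = probes["chromatin_state"].isin(_OPEN_STATES).to_numpy()
            weight = weight * np.where(open_chrom, 3.0, 1.0)
    elif profile == "si_like":
        weight = np.where((baseline >= 0.35) & (baseline <= 0.80), 1.0, 1e-6)
    else:  # x_like
        weight = np.where(baseline > 0.50, 1.0, 1e-6)
    weight = weight / weight.sum()
    n_planted = config.n_dose_probes + config.n_drift_probes + config.n_both_probes
    if n_planted > n:
        raise ValueError("more planted probes than probes")
    dose_idx = rng.choice(n, size=config.n_dose_probes, replace=False, p=weight)
    remaining = np.setdiff1d(np.arange(n), dose_idx)
    drift_pick = rng.choice(
        len(remaining), size=config.n_drift_probes + config.n_both_probes, replace=False
    )
    drift_idx = remaining[drift_pick[: config.n_drift_probes]]
    both_idx = remaining[drift_pick[config.n_drift_probes :]]
    return dose_idx, drift_idx, both_idx


def generate_intensities(
    config: SimulationConfig,
    sheet: pd.DataFrame,
    probes: pd.DataFrame,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Intensity matrices with planted dose effects, drift, and batch structure.

    The latent beta of probe p in sample s is

        baseline(p) + effect(p) * dose(s)          [dose-responsive probes]
        + drift_rate * time(s) * direction(p)      [drift probes]
        + chip intercept + row effect + noise,

    clamped to [0.001, 0.999].  When ``residual_sd`` is zero the methylated
    signal is the deterministic M = beta * total_intensity; otherwise M is
    binomial(total_intensity, beta).  U = total - M.  Detection p-values
    are drawn so that a ``detection_fail_rate`` fraction exceed 0.001.

    Returns (intensities, truth) where truth records per-probe baselines,
    planted classes, directions and effect sizes.
    """
    if len(sheet) == 0 or len(probes) == 0:
        raise ValueError("sheet and probes must be non-empty")
    rng = _rng(config.seed, _STREAM_INTENSITIES)
    n_probes, n_samples = len(probes), len(sheet)

    if config.baseline_constant is not None:
        baseline = np.full(n_probes, float(config.baseline_constant))
    else:
        baseline = _draw_baselines(probes, config.baseline_mixture, rng)

    dose_idx, drift_idx, both_idx = _select_effect_probes(config, probes, baseline, rng)
    dose_like = np.concatenate([dose_idx, both_idx])
    drift_like = np.concatenate([drift_idx, both_idx])

    profile = config.effect_profile
    if profile == "fe_like":
        dose_dir = np.ones(len(dose_like))
    elif profile == "x_like":
        dose_dir = -np.ones(len(dose_like))
    else:
        dose_dir = rng.choice([-1.0, 1.0], size=len(dose_like))
    drift_dir = rng.choice([-1.0, 1.0], size=len(drift_like))

    dose = sheet["dose"].to_numpy(float)
    time = sheet["time"].to_numpy(float)
    chips = sheet["chip"].to_numpy()
    rows = sheet["row"].to_numpy()

    latent = np.tile(baseline[:, None], (1, n_samples))
    latent[dose_like] += (config.dose_effect * dose_dir)[:, None] * dose[None, :]
    latent[drift_like] += (config.drift_rate * drift_dir)[:, None] * time[None, :]

    chip_levels, chip_codes = np.unique(chips, return_inverse=True)
    row_levels, row_codes = np.unique(rows, return_inverse=True)
    if config.chip_sd > 0:
        chip_eff = rng.normal(0.0, config.chip_sd, size=(n_probes, len(chip_levels)))
        latent += chip_eff[:, chip_codes]
    if config.row_sd > 0:
        row_eff = rng.normal(0.0, config.row_sd, size=(n_probes, len(row_levels)))
        latent += row_eff[:, row_codes]
    if config.residual_sd > 0:
        latent += rng.normal(0.0, config.residual_sd, size=latent.shape)
    latent = np.clip(latent, 0.001, 0.999)

    total = config.total_intensity
    if config.residual_sd == 0:
        M = latent * total
    else:
        M = rng.binomial(int(round(total)), latent).astype(float)
    U = total - M

    fail = rng.random(latent.shape) < config.detection_fail_rate
    detection_p = np.where(
        fail,
        rng.uniform(0.0011, 1.0, size=latent.shape),
        rng.uniform(0.0, 0.001, size=latent.shape),
    )

    pid = probes["probe_id"].to_numpy()
    cols = sheet.index
    intensities = IntensityMatrix(
        M=pd.DataFrame(M, index=pid, columns=cols),
        U=pd.DataFrame(U, index=pid, columns=cols),
        detection_p=pd.DataFrame(detection_p, index=pid, columns=cols),
    )

    truth = pd.DataFrame(
        {"probe_id": pid, "baseline": baseline, "is_dose": False, "is_drift": False},
    ).set_index("probe_id")
    truth["dose_direction"] = 0.0
    truth["dose_effect"] = 0.0
    truth["drift_direction"] = 0.0
    truth.iloc[dose_like, truth.columns.get_loc("is_dose")] = True
    truth.iloc[drift_like, truth.columns.get_loc("is_drift")] = True
    truth.iloc[dose_like, truth.columns.get_loc("dose_direction")] = dose_dir
    truth.iloc[dose_like, truth.columns.get_loc("dose_effect")] = config.dose_effect * dose_dir
    truth.iloc[drift_like, truth.columns.get_loc("drift_direction")] = drift_dir
    return intensities, truth


# ---------------------------------------------------------------------------
# tumor/normal beta matrices
# ---------------------------------------------------------------------------

def generate_tumor_normal(
    n_probes: int,
    n_pairs: int,
    signature_size: int,
    delta: float,
    noise_sd: float,
    seed: int,
    patient_sd: float = 0.10,
    baseline_mixture: BaselineMixture | None = None,
) -> tuple[pd.DataFrame, pd.Series, list]:
    """Paired tumor/normal beta matrices with a planted discriminating signature.

    Tumor columns shift by ``delta`` (sign drawn per probe, shared across
    patients) at signature probes only.  Each pair carries a patient-level
    random effect (sd ``patient_sd``) shared by its tumor and normal sample
    at every probe -- the inter-individual variation that makes random
    probe subsets cluster by patient rather than by tissue, as on real
    arrays.  Signature-probe baselines are drawn away from the [0, 1]
    boundary so the planted shift never saturates.

    Returns (beta, labels, signature_probe_ids); columns are interleaved
    normal/tumor per patient, labels is a Series mapping sample -> class.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 tumor/normal pairs for clustering")
    if signature_size > n_probes:
        raise ValueError("signature_size exceeds n_probes")
    if not -1.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [-1, 1]")
    mixture = baseline_mixture or BaselineMixture()
    rng = _rng(seed, _STREAM_TUMOR)

    baseline = _draw_baselines(pd.DataFrame(index=range(n_probes)), mixture, rng)
    sig_idx = rng.choice(n_probes, size=signature_size, replace=False)
    mag = abs(delta)
    sign = rng.choice([-1.0, 1.0], size=signature_size)
    # headroom so baseline + shift stays inside [0, 1]
    lo = np.where(sign > 0, 0.05, 0.05 + mag)
    hi = np.where(sign > 0, 0.95 - mag, 0.95)
    baseline[sig_idx] = rng.uniform(lo, hi)

    patient = rng.normal(0.0, patient_sd, size=(n_probes, n_pairs)) if patient_sd > 0 else 0.0
    shift = np.zeros(n_probes)
    shift[sig_idx] = mag * sign

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    data, labels, columns = [], [], []
    for j in range(n_pairs):
        pat = patient[:, j] if np.ndim(patient) else 0.0
        for tissue in ("normal", "tumor"):
            values = baseline + pat
            if tissue == "tumor":
                values = values + shift
            if noise_sd > 0:
                values = values + rng.normal(0.0, noise_sd, size=n_probes)
            data.append(np.clip(values, 0.0, 1.0))
            columns.append(f"{tissue}_{j + 1:02d}")
            labels.append(tissue)
    beta = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=columns)
    labels = pd.Series(labels, index=columns, name="tissue")
    signature = [probe_ids[i] for i in sorted(sig_idx)]
    return beta, labels, signature


# ---------------------------------------------------------------------------
# read intervals
# ---------------------------------------------------------------------------

def generate_read_intervals(
    targets: pd.DataFrame,
    n_reads: int,
    enrichment: float,
    read_length: int,
    seed: int,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """BED-like read intervals, uniform with an enrichment-fold excess of
    read starts inside the target intervals.

    targets : DataFrame (chrom, start, end); assumed non-overlapping and on
              one chromosome.  ``genome_length`` defaults to twice the
              rightmost target end.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = _rng(seed, _STREAM_READS)
    chrom = targets["chrom"].iloc[0] if len(targets) else CHROM
    if genome_length is None:
        genome_length = 2 * int(targets["end"].max()) if len(targets) else 1_000_000

    tgt = targets.sort_values("start") if len(targets) else targets
    t_starts = tgt["start"].to_numpy() if len(tgt) else np.array([], dtype=int)
    t_ends = tgt["end"].to_numpy() if len(tgt) else np.array([], dtype=int)
    t_lengths = t_ends - t_starts
    target_len = int(t_lengths.sum())
    background_len = genome_length - target_len
    p_target = enrichment * target_len / (enrichment * target_len + background_len)

    # complement intervals for background sampling
    comp = []
    cursor = 0
    for s, e in zip(t_starts, t_ends):
        if s > cursor:
            comp.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < genome_length:
        comp.append((cursor, genome_length))
    c_starts = np.array([c[0] for c in comp], dtype=int)
    c_lengths = np.array([c[1] - c[0] for c in comp], dtype=int)

    starts = np.empty(n_reads, dtype=int)
    in_target = rng.random(n_reads) < p_target
    n_in = int(in_target.sum())
    if n_in and target_len:
        which = rng.choice(len(t_starts), size=n_in, p=t_lengths / target_len)
        starts[in_target] = t_starts[which] + rng.integers(0, t_lengths[which])
    n_out = n_reads - n_in
    if n_out:
        which = rng.choice(len(c_starts), size=n_out, p=c_lengths / c_lengths.sum())
        starts[~in_target] = c_starts[which] + rng.integers(0, c_lengths[which])
    starts = np.sort(starts)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + read_length})
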
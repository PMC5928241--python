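"""Genomic and chromatin-context annotation of array probes.

Places CpG probes relative to CpG islands (island / 5' shore / 3' shore /
gene body / other), transcription start sites, and chromatin-state
segmentations; computes compartment enrichment of affected probe sets by
Fisher's exact test; and builds read ("tag") density profiles around probe
sets.

Coordinate conventions: interval annotations are BED-style 0-based,
half-open.  Probe positions arrive 1-based (array-manifest style) and are
converted internally.  Shores are ``shore_width`` (default 2,000) bp from
the island edge; 5'/3' is resolved by the strand of the gene whose TSS lies
nearest the island.  The gene body runs from the downstream (3') shore edge
to the transcription end site.  Category precedence is
Island > Shore > GeneBody > Other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeAnnotation",
    "DEFAULT_STATE_LABELS",
    "DEFAULT_MERGE_MAP",
    "assign_cgi_category",
    "signed_tss_distance",
    "nearest_gene",
    "scaled_island_coordinate",
    "assign_chromatin_state",
    "fisher_exact_2x2",
    "compartment_enrichment",
    "tag_density_profile",
    "set_overlap",
    "annotate_probes",
]

#: raw chromatin-state labels (ChromHMM-style numbering)
DEFAULT_STATE_LABELS = {
    1: "Active Promoter",
    2: "Weak Promoter",
    3: "Poised Promoter",
    4: "Strong Enhancer",
    5: "Strong Enhancer",
    6: "Weak Enhancer",
    7: "Weak Enhancer",
    8: "Insulator",
    9: "Transcriptional Transition",
    10: "Transcriptional Elongation",
    11: "Weak Transcription",
    12: "Polycomb Repressed",
    13: "Heterochromatin",
}

#: merge table: strong-enhancer states pooled, weak-enhancer states pooled,
#: and the three transcription-associated states pooled as one compartment
DEFAULT_MERGE_MAP = {
    4: "Strong Enhancer",
    5: "Strong Enhancer",
    6: "Weak Enhancer",
    7: "Weak Enhancer",
    9: "Transcribed Regions",
    10: "Transcribed Regions",
    11: "Transcribed Regions",
}


@dataclass
class GenomeAnnotation:
    """Interval annotations: CpG islands, gene models, chromatin segments.

    cgi       : DataFrame (chrom, start, end), 0-based half-open, non-overlapping
    genes     : DataFrame (chrom, tss, tes, strand, gene_id); tss/tes are 0-based
                positions; for '-' genes tss > tes
    chromatin : DataFrame (chrom, start, end, state); segments tile each
                chromosome without overlap
    """

    cgi: pd.DataFrame
    genes: pd.DataFrame
    chromatin: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols in (
            (self.cgi, ["chrom", "start", "end"]),
            (self.genes, ["chrom", "tss", "tes", "strand", "gene_id"]),
            (self.chromatin, ["chrom", "start", "end", "state"]),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"annotation table missing columns {missing}")
        if not set(self.genes["strand"]).issubset({"+", "-"}):
            raise ValueError("gene strand must be '+' or '-'")
        if (self.genes["tss"] == self.genes["tes"]).any():
            raise ValueError("gene TSS must differ from TES")


def _interval_distance(p0: int, start: int, end: int) -> int:
    """Distance in bp from position to half-open interval [start, end); 0 if inside."""
    if start <= p0 < end:
        return 0
    if p0 < start:
        return start - p0
    return p0 - end + 1


def _nearest_interval(p0: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Index of the nearest interval (sorted, non-overlapping); ties to the
    interval with the smaller start."""
    i = int(np.searchsorted(starts, p0, side="right")) - 1
    best, best_d = None, None
    for j in (i, i + 1):
        if 0 <= j < len(starts):
            d = _interval_distance(p0, starts[j], ends[j])
            if best_d is None or d < best_d:
                best, best_d = j, d
    return best


def _island_orientation(
    island_start: int, island_end: int, genes: pd.DataFrame, max_gene_dist: int = 10_000
):
    """Strand and gene record of the gene whose TSS is nearest the island.

    Islands with no gene TSS within ``max_gene_dist`` bp default to genomic
    orientation (left edge = 5').  Ties break toward the smaller gene id.
    """
    if len(genes) == 0:
        return "+", None
    d = np.array(
        [_interval_distance(int(t), island_start, island_end) for t in genes["tss"]]
    )
    order = np.lexsort((genes["gene_id"].to_numpy(), d))
    j = order[0]
    if d[j] > max_gene_dist:
        return "+", None
    return genes["strand"].iloc[j], genes.iloc[j]


def assign_cgi_category(
    probe_chrom: str,
    probe_pos: int,
    annotation: GenomeAnnotation,
    shore_width: int = 2000,
    max_gene_dist: int = 10_000,
) -> str:
    """CGI-relative category of one probe: Island, Shore5, Shore3, GeneBody, Other.

    ``probe_pos`` is the 1-based manifest coordinate.  Shores are measured
    from the edges of the *nearest* island; 5'/3' follows the strand of the
    island-associated gene; the gene body runs from the 3' shore edge to
    that gene's TES.
    """
    p0 = int(probe_pos) - 1
    islands = annotation.cgi[annotation.cgi["chrom"] == probe_chrom]
    if len(islands) == 0:
        warnings.warn(f"no islands on {probe_chrom}; probe categorized as Other")
        return "Other"
    islands = islands.sort_values("start")
    starts = islands["start"].to_numpy()
    ends = islands["end"].to_numpy()
    k = _nearest_interval(p0, starts, ends)
    s, e = int(starts[k]), int(ends[k])
    genes = annotation.genes[annotation.genes["chrom"] == probe_chrom]
    strand, gene = _island_orientation(s, e, genes, max_gene_dist)

    if s <= p0 < e:
        return "Island"
    if s - shore_width <= p0 < s:  # left shore
        return "Shore5" if strand == "+" else "Shore3"
    if e <= p0 < e + shore_width:  # right shore
        return "Shore3" if strand == "+" else "Shore5"
    if gene is not None:
        tes = int(gene["tes"])
        if strand == "+" and e + shore_width <= p0 < tes:
            return "GeneBody"
        if strand == "-" and tes <= p0 < s - shore_width:
            return "GeneBody"
    return "Other"


def signed_tss_distance(probe_chrom: str, probe_pos: int, genes: pd.DataFrame) -> int:
    """Distance to the nearest TSS, oriented to transcription.

    Positive downstream of the TSS in the gene's reading direction,
    negative upstream.  Ties break toward the smaller gene id.
    """
    g = _nearest_tss_gene(probe_chrom, probe_pos, genes)
    p0 = int(probe_pos) - 1
    tss = int(g["tss"])
    return p0 - tss if g["strand"] == "+" else tss - p0


def nearest_gene(probe_chrom: str, probe_pos: int, genes: pd.DataFrame) -> str:
    """Id of the gene with the nearest TSS (ties toward the smaller gene id)."""
    return _nearest_tss_gene(probe_chrom, probe_pos, genes)["gene_id"]


def _nearest_tss_gene(probe_chrom: str, probe_pos: int, genes: pd.DataFrame) -> pd.Series:
    sub = genes[genes["chrom"] == probe_chrom]
    if len(sub) == 0:
        raise ValueError(f"no genes on chromosome {probe_chrom}")
    p0 = int(probe_pos) - 1
    d = np.abs(sub["tss"].to_numpy() - p0)
    order = np.lexsort((sub["gene_id"].to_numpy(), d))
    return sub.iloc[order[0]]


def scaled_island_coordinate(
    probe_chrom: str,
    probe_pos: int,
    islands: pd.DataFrame,
    profile_flank: int = 2500,
    genes: pd.DataFrame | None = None,
    max_gene_dist: int = 10_000,
) -> float:
    """Island-scaled coordinate of a probe near its nearest CpG island.

    The island interior maps to [0, 1] (5' edge = 0.0, 3' edge = 1.0);
    flank positions are bp offsets: ``-b`` for b bp into the 5' flank and
    ``1 + b`` for b bp into the 3' flank.  Probes beyond ``profile_flank``
    of the island return NaN.  Orientation follows the island-associated
    gene when ``genes`` is supplied, else the genomic left edge is 5'.
    """
    p0 = int(probe_pos) - 1
    sub = islands[islands["chrom"] == probe_chrom].sort_values("start")
    if len(sub) == 0:
        return float("nan")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    k = _nearest_interval(p0, starts, ends)
    s, e = int(starts[k]), int(ends[k])
    width = e - s
    if width <= 0:
        raise ValueError("zero-width island")
    strand = "+"
    if genes is not None:
        strand, _ = _island_orientation(s, e, genes[genes["chrom"] == probe_chrom], max_gene_dist)

    if strand == "+":
        if s <= p0 <= e:
            return (p0 - s) / width
        if s - profile_flank <= p0 < s:
            return -float(s - p0)
        if e < p0 <= e + profile_flank:
            return 1.0 + float(p0 - e)
    else:
        if s <= p0 <= e:
            return (e - p0) / width
        if e < p0 <= e + profile_flank:
            return -float(p0 - e)
        if s - profile_flank <= p0 < s:
            return 1.0 + float(s - p0)
    return float("nan")


def assign_chromatin_state(
    probe_chrom: str,
    probe_pos: int,
    segments: pd.DataFrame,
    merge_map: dict | None = None,
    state_labels: dict | None = None,
) -> str:
    """Chromatin-state label of a probe, after merging related states.

    The raw state is looked up by interval membership in the tiling
    segmentation, then mapped through the merge table (strong-enhancer
    states pooled; weak-enhancer states pooled; the three transcription
    states pooled as 'Transcribed Regions').  A probe covered by no segment
    returns 'Unassigned' with a warning.
    """
    merge_map = DEFAULT_MERGE_MAP if merge_map is None else merge_map
    state_labels = DEFAULT_STATE_LABELS if state_labels is None else state_labels
    p0 = int(probe_pos) - 1
    sub = segments[segments["chrom"] == probe_chrom].sort_values("start")
    if len(sub):
        starts = sub["start"].to_numpy()
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        if i >= 0 and p0 < int(sub["end"].iloc[i]):
            raw = sub["state"].iloc[i]
            if raw in merge_map:
                return merge_map[raw]
            return state_labels.get(raw, str(raw))
    warnings.warn(f"probe at {probe_chrom}:{probe_pos} covered by no chromatin segment")
    return "Unassigned"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher's exact p for one 2x2 table.

    The p-value is the probability mass of all tables (fixed margins) at
    least as extreme as the observed one, i.e. with hypergeometric
    probability no larger than the observed table's.
    """
    _, p = stats.fisher_exact(np.array([[a, b], [c, d]]), alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return odds, float(p)


def compartment_enrichment(
    affected: set | list,
    universe: set | list,
    states: pd.Series,
) -> pd.DataFrame:
    """Per-state enrichment of an affected probe set against the array universe.

    For each state a 2x2 table is formed: affected vs (universe minus
    affected) by in-state vs not-in-state.  Returns the sample odds ratio
    (a*d)/(b*c), a Woolf (log-OR normal approximation) 95% CI with a 0.5
    continuity correction applied when any cell is zero, and the two-sided
    Fisher's exact p-value.
    """
    affected = set(affected)
    universe = set(universe)
    if not affected:
        raise ValueError("affected set is empty")
    if not affected <= universe:
        raise ValueError("affected probes must be a subset of the universe")
    states = states[states.index.isin(universe)]
    rows = []
    n_aff = len(affected)
    n_uni = len(universe)
    for state in sorted(states.unique()):
        in_state = set(states.index[states == state])
        if not in_state:
            warnings.warn(f"state {state!r} empty in universe; skipped")
            continue
        a = len(affected & in_state)
        b = n_aff - a
        c = len(in_state) - a
        d = (n_uni - n_aff) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        aa, bb, cc, dd = (x + 0.5 if min(a, b, c, d) == 0 else x for x in (a, b, c, d))
        log_or = np.log((aa * dd) / (bb * cc))
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        rows.append(
            {
                "state": state,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "ci_low": float(np.exp(log_or - 1.959963984540054 * se)),
                "ci_high": float(np.exp(log_or + 1.959963984540054 * se)),
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows)


def tag_density_profile(
    reads: pd.DataFrame,
    probes: pd.DataFrame,
    half_window: int,
    bin_width: int = 20,
    total_mapped: int | None = None,
) -> pd.DataFrame:
    """Average read ("tag") density around a probe set, in fixed-width bins.

    For each probe, reads overlapping (by >= 1 bp) each ``bin_width`` bin in
    [pos - half_window, pos + half_window) are counted; counts are averaged
    over probes and scaled to reads per bin per million mapped reads.

    reads  : DataFrame (chrom, start, end), 0-based half-open
    probes : DataFrame (chrom, pos) with 1-based positions
    Returns a DataFrame (offset, density); offsets are bin centers relative
    to the probe position.
    """
    if half_window % bin_width:
        raise ValueError("half_window must be a multiple of bin_width")
    if len(probes) == 0:
        raise ValueError("empty probe set")
    if total_mapped is None:
        total_mapped = len(reads)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    n_bins = 2 * half_window // bin_width
    counts = np.zeros(n_bins)
    by_chrom = {
        chrom: (
            np.sort(sub["start"].to_numpy()),
            np.sort(sub["end"].to_numpy()),
        )
        for chrom, sub in reads.groupby("chrom")
    }
    for _, probe in probes.iterrows():
        got = by_chrom.get(probe["chrom"])
        if got is None:
            continue
        starts_sorted, ends_sorted = got
        p0 = int(probe["pos"]) - 1
        edges = p0 - half_window + bin_width * np.arange(n_bins + 1)
        # reads overlap bin [lo, hi) iff start < hi and end > lo
        n_start_before = np.searchsorted(starts_sorted, edges[1:], side="left")
        n_end_before = np.searchsorted(ends_sorted, edges[:-1], side="right")
        counts += n_start_before - n_end_before
    density = counts / len(probes) / (total_mapped / 1e6)
    offsets = -half_window + bin_width * np.arange(n_bins) + bin_width / 2.0
    return pd.DataFrame({"offset": offsets, "density": density})


def set_overlap(set_a, set_b) -> tuple[int, int, int]:
    """(|A and B|, |A only|, |B only|) by exact set algebra."""
    a, b = set(set_a), set(set_b)
    return len(a & b), len(a - b), len(b - a)


def annotate_probes(
    probes: pd.DataFrame,
    annotation: GenomeAnnotation,
    shore_width: int = 2000,
    merge_map: dict | None = None,
) -> pd.DataFrame:
    """Tabulate CGI category, nearest gene, signed TSS distance, and
    chromatin state for every probe in a manifest (probe_id, chrom, pos)."""
    records = []
    for _, p in probes.iterrows():
        records.append(
            {
                "probe_id": p["probe_id"],
                "cgi_category": assign_cgi_category(
                    p["chrom"], p["pos"], annotation, shore_width=shore_width
                ),
                "nearest_gene": nearest_gene(p["chrom"], p["pos"], annotation.genes),
                "tss_distance": signed_tss_distance(p["chrom"], p["pos"], annotation.genes),
                "chromatin_state": assign_chromatin_state(
                    p["chrom"], p["pos"], annotation.chromatin, merge_map=merge_map
                ),
            }
        )
    return pd.DataFrame(records).set_index("probe_id")
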
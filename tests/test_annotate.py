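"""Genomic annotation: CGI categories, TSS distances, chromatin states,
enrichment and tag-density profiles, each against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hzemeth import simulate
from hzemeth.annotate import (
    DEFAULT_MERGE_MAP,
    DEFAULT_STATE_LABELS,
    GenomeAnnotation,
    assign_cgi_category,
    assign_chromatin_state,
    compartment_enrichment,
    nearest_gene,
    scaled_island_coordinate,
    set_overlap,
    signed_tss_distance,
    tag_density_profile,
)
from hzemeth.config import SimulationConfig

# ---------------------------------------------------------------------------
# independent linear-scan oracles
# ---------------------------------------------------------------------------


def oracle_cgi_category(chrom, pos, ann, shore=2000, max_gene_dist=10_000):
    """Per-probe linear scan over every island; same precedence rules."""
    p0 = pos - 1
    islands = [
        (s, e) for c, s, e in ann.cgi.itertuples(index=False) if c == chrom
    ]
    if not islands:
        return "Other"
    best, best_d = None, None
    for s, e in islands:
        d = 0 if s <= p0 < e else (s - p0 if p0 < s else p0 - e + 1)
        if best_d is None or d < best_d or (d == best_d and s < best[0]):
            best, best_d = (s, e), d
    s, e = best
    # island-associated gene: nearest TSS to the island, ties by gene id
    cands = []
    for c, tss, tes, strand, gid in ann.genes.itertuples(index=False):
        if c != chrom:
            continue
        d = 0 if s <= tss < e else (s - tss if tss < s else tss - e + 1)
        cands.append((d, gid, strand, tes))
    cands.sort()
    strand, tes = ("+", None)
    if cands and cands[0][0] <= max_gene_dist:
        strand, tes = cands[0][2], cands[0][3]
    if s <= p0 < e:
        return "Island"
    if s - shore <= p0 < s:
        return "Shore5" if strand == "+" else "Shore3"
    if e <= p0 < e + shore:
        return "Shore3" if strand == "+" else "Shore5"
    if tes is not None:
        if strand == "+" and e + shore <= p0 < tes:
            return "GeneBody"
        if strand == "-" and tes <= p0 < s - shore:
            return "GeneBody"
    return "Other"


def oracle_tss(chrom, pos, genes):
    p0 = pos - 1
    best = None
    for c, tss, tes, strand, gid in genes.itertuples(index=False):
        if c != chrom:
            continue
        key = (abs(p0 - tss), gid)
        if best is None or key < best[0]:
            signed = p0 - tss if strand == "+" else tss - p0
            best = (key, signed, gid)
    return best[1], best[2]


def oracle_state(chrom, pos, segments):
    p0 = pos - 1
    for c, s, e, state in segments.itertuples(index=False):
        if c == chrom and s <= p0 < e:
            return DEFAULT_MERGE_MAP.get(state, DEFAULT_STATE_LABELS.get(state, str(state)))
    return "Unassigned"


@pytest.fixture(scope="module")
def layout():
    cfg = SimulationConfig(seed=17, n_probes=1000)
    probes, ann = simulate.generate_probe_annotation(cfg)
    return probes, ann


# ---------------------------------------------------------------------------
# CGI categories
# ---------------------------------------------------------------------------


def _toy_annotation():
    """One island [10000, 11000) whose promoter gene runs + from 10500."""
    return GenomeAnnotation(
        cgi=pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]}),
        genes=pd.DataFrame(
            {
                "chrom": ["chr1"],
                "tss": [10_500],
                "tes": [20_000],
                "strand": ["+"],
                "gene_id": ["g1"],
            }
        ),
        chromatin=pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [30_000], "state": [1]}
        ),
    )


class TestCgiCategory:
    def test_island_midpoint(self):
        assert assign_cgi_category("chr1", 10_501, _toy_annotation()) == "Island"

    def test_upstream_shore_boundaries(self):
        ann = _toy_annotation()
        # 500 bp upstream of the left edge of a '+' oriented island
        assert assign_cgi_category("chr1", 10_000 - 500 + 1, ann) == "Shore5"
        # 2,500 bp upstream is beyond the 2 kb shore
        assert assign_cgi_category("chr1", 10_000 - 2_500 + 1, ann) != "Shore5"

    def test_gene_body_region(self):
        ann = _toy_annotation()
        assert assign_cgi_category("chr1", 14_001, ann) == "GeneBody"  # past 3' shore
        assert assign_cgi_category("chr1", 25_001, ann) == "Other"  # past the TES

    def test_minus_strand_shores_flip(self):
        ann = _toy_annotation()
        ann.genes.loc[0, ["strand", "tes"]] = ["-", 2_000]
        assert assign_cgi_category("chr1", 10_000 - 500 + 1, ann) == "Shore3"
        assert assign_cgi_category("chr1", 11_000 + 500 + 1, ann) == "Shore5"

    def test_absent_chromosome_warns_other(self):
        with pytest.warns(UserWarning):
            assert assign_cgi_category("chrZ", 100, _toy_annotation()) == "Other"

    def test_matches_oracle_on_layout(self, layout):
        probes, ann = layout
        for _, p in probes.iterrows():
            got = assign_cgi_category(p["chrom"], p["pos"], ann)
            assert got == oracle_cgi_category(p["chrom"], p["pos"], ann)

    def test_truth_categories_match_assignment(self, layout):
        """The generator's planted truth labels agree with the annotator."""
        probes, ann = layout
        for _, p in probes.sample(200, random_state=0).iterrows():
            assert assign_cgi_category(p["chrom"], p["pos"], ann) == p["truth_category"]


class TestTssDistance:
    def test_probe_at_tss(self):
        ann = _toy_annotation()
        assert signed_tss_distance("chr1", 10_501, ann.genes) == 0

    def test_strand_reflection(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "tss": [5000], "tes": [9000], "strand": ["+"], "gene_id": ["g1"]}
        )
        assert signed_tss_distance("chr1", 6001, genes) == 1000
        genes["strand"] = "-"
        assert signed_tss_distance("chr1", 6001, genes) == -1000

    def test_tie_breaks_to_smaller_gene_id(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "tss": [4000, 6000],
                "tes": [4500, 9000],
                "strand": ["+", "+"],
                "gene_id": ["gB", "gA"],
            }
        )
        # probe equidistant (1000 bp) from both TSSs
        assert nearest_gene("chr1", 5001, genes) == "gA"

    def test_matches_oracle_on_layout(self, layout):
        probes, ann = layout
        for _, p in probes.sample(300, random_state=1).iterrows():
            signed, gid = oracle_tss(p["chrom"], p["pos"], ann.genes)
            assert signed_tss_distance(p["chrom"], p["pos"], ann.genes) == signed
            assert nearest_gene(p["chrom"], p["pos"], ann.genes) == gid


class TestScaledIslandCoordinate:
    def test_midpoint_and_edges(self):
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]})
        assert scaled_island_coordinate("chr1", 10_501, islands) == pytest.approx(0.5)
        assert scaled_island_coordinate("chr1", 10_001, islands) == 0.0
        assert scaled_island_coordinate("chr1", 11_001, islands) == 1.0

    def test_flank_offsets(self):
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]})
        got = scaled_island_coordinate("chr1", 10_000 - 1250 + 1, islands, profile_flank=2500)
        assert got == -1250.0
        got = scaled_island_coordinate("chr1", 11_000 + 400 + 1, islands, profile_flank=2500)
        assert got == 1.0 + 400

    def test_outside_window_is_nan(self):
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]})
        assert np.isnan(scaled_island_coordinate("chr1", 100, islands, profile_flank=2500))

    def test_zero_width_island_errors(self):
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_000]})
        with pytest.raises(ValueError):
            scaled_island_coordinate("chr1", 10_001, islands)


class TestChromatinState:
    def test_transcription_states_merge(self):
        segments = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "state": [10]}
        )
        assert assign_chromatin_state("chr1", 500, segments) == "Transcribed Regions"

    def test_unmerged_state_label_unchanged(self):
        segments = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "state": [1]}
        )
        assert assign_chromatin_state("chr1", 500, segments) == "Active Promoter"

    def test_uncovered_probe_warns(self):
        segments = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "state": [1]}
        )
        with pytest.warns(UserWarning):
            assert assign_chromatin_state("chr1", 5000, segments) == "Unassigned"

    def test_matches_oracle_on_layout(self, layout):
        probes, ann = layout
        for _, p in probes.sample(300, random_state=2).iterrows():
            got = assign_chromatin_state(p["chrom"], p["pos"], ann.chromatin)
            assert got == oracle_state(p["chrom"], p["pos"], ann.chromatin)


class TestEnrichment:
    def test_known_odds_ratio(self):
        """30/100 affected in state vs 970/9900 others: OR ~ 3.95, exact p."""
        universe = [f"p{i}" for i in range(10_000)]
        states = pd.Series("closed", index=universe)
        states.iloc[:30] = "open"  # affected, in state
        states.iloc[100:1070] = "open"  # not affected, in state
        affected = universe[:100]
        table = compartment_enrichment(affected, universe, states)
        row = table[table["state"] == "open"].iloc[0]
        assert row["a"] == 30 and row["c"] == 970
        assert row["odds_ratio"] == pytest.approx((30 * 8930) / (70 * 970), rel=1e-12)
        expected_p = stats.fisher_exact([[30, 70], [970, 8930]])[1]
        assert row["fisher_p"] == pytest.approx(expected_p, rel=1e-12)
        assert row["a"] + row["b"] + row["c"] + row["d"] == 10_000

    def test_equal_proportions_null(self):
        universe = [f"p{i}" for i in range(200)]
        states = pd.Series(["open"] * 50 + ["closed"] * 150, index=universe)
        affected = universe[:10] + universe[50:80]  # 10/40 open = 50/200 overall
        table = compartment_enrichment(affected, universe, states)
        row = table[table["state"] == "open"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["fisher_p"] == pytest.approx(1.0)

    def test_planted_enhancer_bias_detected(self):
        """A 3x enhancer-share affected set gives OR > 1, p < 0.01 nearly always."""
        universe = [f"p{i}" for i in range(5000)]
        states = pd.Series(["enhancer"] * 500 + ["other"] * 4500, index=universe)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            weights = np.where(states == "enhancer", 3.0, 1.0)
            affected = rng.choice(universe, size=150, replace=False, p=weights / weights.sum())
            table = compartment_enrichment(affected, universe, states)
            row = table[table["state"] == "enhancer"].iloc[0]
            hits += (row["odds_ratio"] > 1) and (row["fisher_p"] < 0.01)
        assert hits >= 95

    def test_woolf_ci_brackets_or(self):
        universe = [f"p{i}" for i in range(1000)]
        states = pd.Series(["a"] * 300 + ["b"] * 700, index=universe)
        affected = universe[:60] + universe[300:340]  # 60 in 'a', 40 in 'b'
        table = compartment_enrichment(affected, universe, states)
        for _, row in table.iterrows():
            assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]


class TestTagDensity:
    def test_single_read_single_bin(self):
        reads = pd.DataFrame({"chrom": ["chrS"], "start": [1000], "end": [1020]})
        # probe at p0=1000: window [900, 1100) puts the read exactly in bin [1000, 1020)
        probes = pd.DataFrame({"chrom": ["chrS"], "pos": [1001]})
        prof = tag_density_profile(reads, probes, half_window=100, bin_width=20,
                                   total_mapped=1_000_000)
        hot = prof[prof["density"] > 0]
        assert len(hot) == 1
        assert hot["density"].iloc[0] == pytest.approx(1.0)

    def test_uniform_reads_flat_profile(self):
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 100_000, 20_000)
        reads = pd.DataFrame({"chrom": "chrS", "start": starts, "end": starts + 36})
        probes = pd.DataFrame({"chrom": ["chrS"] * 20, "pos": rng.integers(20_000, 80_000, 20)})
        prof = tag_density_profile(reads, probes, half_window=1000, bin_width=20)
        d = prof["density"].to_numpy()
        # flat profile: bin-to-bin scatter stays small relative to the mean
        assert d.std(ddof=1) < 0.15 * d.mean()

    def test_linearity_in_reads(self):
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 50_000, 2_000)
        reads = pd.DataFrame({"chrom": "chrS", "start": starts, "end": starts + 36})
        probes = pd.DataFrame({"chrom": ["chrS"] * 5, "pos": rng.integers(10_000, 40_000, 5)})
        single = tag_density_profile(reads, probes, 500, total_mapped=len(reads))
        doubled = tag_density_profile(
            pd.concat([reads, reads]), probes, 500, total_mapped=2 * len(reads)
        )
        np.testing.assert_allclose(doubled["density"], single["density"])

    def test_enriched_center(self):
        """Generator targets centered on probes: central bins ~10x the edges."""
        probes = pd.DataFrame({"chrom": ["chrS"] * 10, "pos": np.arange(50_000, 150_000, 10_000)})
        targets = pd.DataFrame(
            {"chrom": "chrS", "start": probes["pos"] - 200, "end": probes["pos"] + 200}
        )
        reads = simulate.generate_read_intervals(
            targets, 100_000, 10.0, 36, seed=3, genome_length=200_000
        )
        prof = tag_density_profile(reads, probes, half_window=2000, bin_width=20)
        center = prof[np.abs(prof["offset"]) < 150]["density"].mean()
        edges = prof[np.abs(prof["offset"]) > 1500]["density"].mean()
        assert center / edges == pytest.approx(10.0, rel=0.2)

    def test_empty_probe_set_errors(self):
        reads = pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [36]})
        with pytest.raises(ValueError):
            tag_density_profile(reads, reads.iloc[:0], 100)


class TestSetOverlap:
    def test_basic(self):
        assert set_overlap({"g1", "g2"}, {"g2", "g3"}) == (1, 1, 1)

    def test_identical(self):
        assert set_overlap({"a", "b", "c"}, {"a", "b", "c"}) == (3, 0, 0)

    def test_random_against_bruteforce(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = set(rng.choice(100, rng.integers(1, 50), replace=False))
            b = set(rng.choice(100, rng.integers(1, 50), replace=False))
            inter = sum(1 for x in a if x in b)
            assert set_overlap(a, b) == (inter, len(a) - inter, len(b) - inter)
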
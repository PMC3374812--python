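import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from amplimark.io import validate_clinical
from amplimark.regions import (
    AmpliconDefinition,
    WindowConfig,
    bh_adjust,
    call_amplicons_per_sample,
    define_amplicons,
    hypergeometric_enrichment,
    make_windows,
    stratified_outcome,
)


def _annotation(n, chrom="chr1"):
    return pd.DataFrame(
        {"gene_id": [f"g{i:04d}" for i in range(n)], "chrom": chrom,
         "start": 1000 * np.arange(1, n + 1), "end": 1000 * np.arange(1, n + 1) + 10,
         "cytoband": [f"1q{i // 25 + 1}" for i in range(n)]}
    )


class TestWindows:
    def test_enumeration_with_end_anchor(self):
        windows = make_windows(_annotation(60), WindowConfig(width=25, pace=5))
        starts = [w.start_index for w in windows]
        assert starts == [0, 5, 10, 15, 20, 25, 30, 35]
        assert (windows[-1].start_index, windows[-1].stop_index) == (35, 60)

    def test_exact_width_gives_single_window(self):
        windows = make_windows(_annotation(25), WindowConfig(width=25, pace=5))
        assert len(windows) == 1
        assert (windows[0].start_index, windows[0].stop_index) == (0, 25)

    def test_short_chromosome_gives_one_covering_window(self):
        windows = make_windows(_annotation(10), WindowConfig(width=25, pace=5))
        assert len(windows) == 1
        assert windows[0].stop_index == 10

    def test_every_gene_covered(self):
        windows = make_windows(_annotation(63), WindowConfig(width=25, pace=5))
        covered = set()
        for w in windows:
            covered.update(range(w.start_index, w.stop_index))
        assert covered == set(range(63))

    def test_invalid_pace_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(width=5, pace=6)


class TestHypergeometricEnrichment:
    def test_zero_overlap_gives_p_one(self):
        res = hypergeometric_enrichment(["a"], ["b"], ["a", "b", "c"])
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_summation(self):
        universe = [f"u{i}" for i in range(1000)]
        cluster = universe[:50]
        window = universe[:10] + universe[50:65]  # overlap 10, size 25
        res = hypergeometric_enrichment(cluster, window, universe)
        expected = sum(comb(50, k) * comb(950, 25 - k) for k in range(10, 26)) / comb(1000, 25)
        assert res["p"] == pytest.approx(expected, rel=1e-10)

    def test_window_equal_to_universe_gives_p_one(self):
        uni = [f"u{i}" for i in range(30)]
        res = hypergeometric_enrichment(uni[:5], uni, uni)
        assert res["p"] == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], [], [])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_fixed_margin_enumeration(self, seed):
        # brute-force: enumerate every subset size of overlap for small N
        rng = np.random.default_rng(seed)
        n_universe = int(rng.integers(10, 60))
        universe = [f"u{i}" for i in range(n_universe)]
        n_set = int(rng.integers(1, n_universe))
        n_target = int(rng.integers(1, n_universe))
        s = list(rng.choice(universe, n_set, replace=False))
        t = list(rng.choice(universe, n_target, replace=False))
        k_obs = len(set(s) & set(t))
        total = comb(n_universe, n_set)
        p_brute = sum(
            comb(n_target, k) * comb(n_universe - n_target, n_set - k)
            for k in range(k_obs, min(n_set, n_target) + 1)
            if n_set - k <= n_universe - n_target
        ) / total
        res = hypergeometric_enrichment(t, s, universe)
        assert res["p"] == pytest.approx(p_brute, rel=1e-10)


def _naive_bh(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q[idx] = p[idx] * m / rank
    # enforce monotonicity from the largest p down
    for i in range(m - 2, -1, -1):
        q[order[i]] = min(q[order[i]], q[order[i + 1]])
    return np.minimum(q, 1.0)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_with_monotone_correction(self):
        q = bh_adjust([0.001, 0.02, 0.04, 0.05])
        assert q == pytest.approx([0.004, 0.04, 0.05, 0.05])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_step_up(self, seed):
        p = np.random.default_rng(seed).random(50)
        assert bh_adjust(p) == pytest.approx(_naive_bh(p), rel=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDefineAmplicons:
    def test_planted_run_recovered_exactly(self):
        ann = _annotation(2000)
        cluster = ann["gene_id"][500:525].tolist()
        defs, enrich = define_amplicons(cluster, ann, ann["gene_id"])
        assert len(defs) == 1
        assert set(cluster) == set(defs[0].marker_genes)

    def test_overlapping_significant_windows_merge(self):
        ann = _annotation(100)
        cluster = ann["gene_id"][0:30].tolist()  # spans windows [0,25) and [5,30)
        defs, _ = define_amplicons(cluster, ann, ann["gene_id"])
        assert len(defs) == 1
        assert defs[0].start_index == 0 and defs[0].stop_index >= 30

    def test_no_signal_gives_empty_list(self):
        ann = _annotation(500)
        rng = np.random.default_rng(0)
        cluster = list(rng.choice(ann["gene_id"], 20, replace=False))
        defs, _ = define_amplicons(cluster, ann, ann["gene_id"])
        assert defs == []

    def test_region_named_by_cytoband_span(self):
        ann = _annotation(2000)
        cluster = ann["gene_id"][10:20].tolist()
        defs, _ = define_amplicons(cluster, ann, ann["gene_id"])
        assert defs and defs[0].name.startswith("1q1")


class TestSampleCalls:
    @staticmethod
    def _b_high(marker_flags, n_extra=20, n_samples=4):
        rows = {f"m{i}": flags for i, flags in enumerate(marker_flags)}
        rng = np.random.default_rng(0)
        for i in range(n_extra):
            rows[f"bg{i}"] = rng.integers(0, 1, n_samples)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"s{j}" for j in range(n_samples)])

    @staticmethod
    def _amp(markers):
        return AmpliconDefinition(name="amp", chrom="chr1", start_index=0, stop_index=len(markers),
                                  start_bp=1, end_bp=2, marker_genes=markers)

    def test_half_of_markers_calls_the_sample(self):
        b = self._b_high([[1, 1, 0, 1], [1, 0, 0, 1], [0, 0, 0, 1], [0, 1, 0, 1]])
        calls = call_amplicons_per_sample(b, [self._amp(["m0", "m1", "m2", "m3"])], mode="fraction")
        # s0: 2/4 called; s1: 2/4 called; s2: 0/4 not; s3: 4/4 called
        assert calls["amp"].tolist() == [1, 1, 0, 1]
        assert calls["any_amplicon"].tolist() == [1, 1, 0, 1]

    def test_below_half_not_called(self):
        b = self._b_high([[1, 0], [0, 0], [0, 0], [0, 0]], n_samples=2)
        calls = call_amplicons_per_sample(b, [self._amp(["m0", "m1", "m2", "m3"])], mode="fraction")
        assert calls["amp"].tolist() == [0, 0]

    def test_call_monotone_in_flags(self):
        rng = np.random.default_rng(1)
        flags = rng.integers(0, 2, (4, 6))
        b = self._b_high(list(flags), n_samples=6)
        amp = [self._amp(["m0", "m1", "m2", "m3"])]
        before = call_amplicons_per_sample(b, amp, mode="fraction")["amp"]
        b2 = b.copy()
        b2.loc["m0"] = 1  # add flags, never remove
        after = call_amplicons_per_sample(b2, amp, mode="fraction")["amp"]
        assert (after >= before).all()

    def test_zero_marker_amplicon_raises(self):
        b = self._b_high([[1, 0]], n_samples=2)
        with pytest.raises(ValueError):
            call_amplicons_per_sample(b, [self._amp([])])

    def test_fisher_mode_separates_carriers(self, fixture_cohort):
        from amplimark.outliers import call_outliers, robust_scale

        expr, ann, clin, truth = fixture_cohort
        scaled, _ = robust_scale(expr)
        pair = call_outliers(scaled)
        amps = [self._amp(genes) for genes in truth.region_genes.values()]
        for i, (name, genes) in enumerate(truth.region_genes.items()):
            amps[i] = AmpliconDefinition(name=name, chrom="chr1", start_index=0,
                                         stop_index=len(genes), start_bp=1, end_bp=2,
                                         marker_genes=genes)
        calls = call_amplicons_per_sample(pair.b_high, amps, mode="fisher")
        truth_any = (truth.carriers.sum(axis=1) > 0)
        called_any = calls["any_amplicon"] == 1
        sens = (called_any & truth_any).sum() / truth_any.sum()
        spec = (~called_any & ~truth_any).sum() / (~truth_any).sum()
        assert sens >= 0.8
        assert spec >= 0.9


class TestStratifiedOutcome:
    @staticmethod
    def _cohort(seed=0, n=500, hr=4.0, prevalence=0.3):
        rng = np.random.default_rng(seed)
        carrier = (rng.random(n) < prevalence).astype(int)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(hr) * carrier)))
        clin = validate_clinical(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)], "time": t,
            "event": np.ones(n, dtype=int),
            "grade": rng.choice(["low", "intermediate", "high"], n)}))
        calls = pd.DataFrame({"amp": carrier, "any_amplicon": carrier}, index=clin.index)
        return calls, clin

    def test_recovers_planted_hazard_ratio(self):
        calls, clin = self._cohort(seed=1)
        table, curves = stratified_outcome(calls, clin)
        hr = table.set_index("amplicon").loc["any_amplicon", "hazard_ratio"]
        assert 3.0 <= hr <= 5.3
        assert set(curves) == {"amp", "any_amplicon"}

    def test_zero_carrier_amplicon_raises(self):
        calls, clin = self._cohort(seed=2)
        calls["amp"] = 0
        calls["any_amplicon"] = 0
        with pytest.raises(ValueError):
            stratified_outcome(calls, clin)

    def test_grade_stratum_without_events_raises(self):
        calls, clin = self._cohort(seed=3)
        clin.loc[clin["grade"] == "low", "event"] = 0
        with pytest.raises(ValueError, match="no events"):
            stratified_outcome(calls, clin, grade="low")

    def test_reference_arm_is_zero_amplicon_samples(self):
        calls, clin = self._cohort(seed=4)
        rng = np.random.default_rng(5)
        other = (rng.random(len(calls)) < 0.3).astype(int)
        calls["amp2"] = other
        calls["any_amplicon"] = ((calls["amp"] + other) > 0).astype(int)
        table, _ = stratified_outcome(calls, clin)
        row = table.set_index("amplicon").loc["amp"]
        assert row["n_reference"] == int((calls["any_amplicon"] == 0).sum())
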
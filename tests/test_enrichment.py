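"""Randomization law, enrichment statistics, control sites, Spearman."""

import numpy as np
import pytest
from scipy import stats

from g4hub.enrichment import (
    Workspace,
    association_test,
    build_control_sites,
    compare_conditions,
    randomize_in_workspace,
    results_to_frame,
    spearman_rho,
)
from g4hub.intervals import GenomicInterval, IntervalSet
from conftest import random_interval_set


def _iv(spans, chrom="chr1", label=""):
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in spans], label=label)


# -- randomization law -------------------------------------------------------

def test_randomized_starts_uniform_over_legal_positions():
    """One segment [0,1000), peak length 100: starts uniform on [0,900]."""
    ws = Workspace(_iv([(0, 1000)]))
    peaks = _iv([(0, 100)] * 10)
    rng = np.random.default_rng(5)
    starts = []
    for _ in range(1000):  # 10 peaks x 1000 draws = 1e4 placements
        rand, n_excl = randomize_in_workspace(peaks, ws, rng=rng)
        assert n_excl == 0
        starts.extend(iv.start for iv in rand)
    starts = np.asarray(starts)
    assert starts.min() >= 0 and starts.max() <= 900
    assert abs(starts.mean() - 450) < 10
    counts, _ = np.histogram(starts, bins=np.linspace(0, 901, 21))
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    assert stats.chi2.sf(chi2, df=len(counts) - 1) > 0.01


def test_randomization_weights_segments_by_legal_starts():
    """A segment below peak length is never used; placements stay legal."""
    ws = Workspace(_iv([(0, 50), (1000, 2000)]))
    peaks = _iv([(0, 100)] * 200)
    rand, n_excl = randomize_in_workspace(peaks, ws, seed=0)
    assert n_excl == 0
    assert all(1000 <= iv.start and iv.end <= 2000 for iv in rand)


def test_oversized_peak_excluded_with_tally():
    ws = Workspace(_iv([(0, 1000)]))
    peaks = _iv([(0, 2000), (0, 100)])
    rand, n_excl = randomize_in_workspace(peaks, ws, seed=1)
    assert n_excl == 1 and len(rand) == 1


def test_all_peaks_excluded_raises():
    ws = Workspace(_iv([(0, 100)]))
    with pytest.raises(ValueError):
        randomize_in_workspace(_iv([(0, 500)]), ws, seed=1)


def test_randomization_deterministic_under_seed():
    ws = Workspace(_iv([(0, 5000), (8000, 9000)]))
    peaks = _iv([(0, 100), (200, 260), (300, 420)])
    a, _ = randomize_in_workspace(peaks, ws, seed=42)
    b, _ = randomize_in_workspace(peaks, ws, seed=42)
    assert a == b


# -- association test --------------------------------------------------------

def test_subject_tiling_workspace_gives_fold_one_p_one():
    ws = Workspace(_iv([(0, 10_000)]))
    query = _iv([(100, 150), (2000, 2100), (9000, 9050)], label="q")
    subject = _iv([(0, 10_000)], label="tiling")
    (res,) = association_test(query, [subject], ws, n_randomizations=200, seed=3)
    assert res.observed == len(query)
    assert res.null_mean == len(query) and res.null_sd == 0
    assert res.fold == 1.0
    assert res.p_enrich == 1.0


def test_empty_subject_flagged_undefined():
    ws = Workspace(_iv([(0, 10_000)]))
    query = _iv([(100, 150)], label="q")
    (res,) = association_test(query, [IntervalSet([], label="none")], ws,
                              n_randomizations=100, seed=3)
    assert res.undefined and np.isnan(res.fold)


def test_null_ensemble_shared_across_subjects():
    """Per-subject results do not depend on which other subjects are present."""
    rng = np.random.default_rng(8)
    ws = Workspace(_iv([(0, 10_000)]))
    query = random_interval_set(rng, n=30, max_width=80, label="q")
    a = random_interval_set(rng, n=40, max_width=120, label="A")
    b = random_interval_set(rng, n=40, max_width=120, label="B")
    res_ab = association_test(query, [a, b], ws, n_randomizations=150, seed=9)
    res_ba = association_test(query, [b, a], ws, n_randomizations=150, seed=9)
    res_a = association_test(query, [a], ws, n_randomizations=150, seed=9)
    by_label = {r.subject_label: r for r in res_ba}
    for r in res_ab:
        s = by_label[r.subject_label]
        assert (r.observed, r.null_mean, r.fold, r.p_enrich) == \
               (s.observed, s.null_mean, s.fold, s.p_enrich)
    assert res_a[0].fold == by_label["A"].fold


def test_low_n_warns():
    ws = Workspace(_iv([(0, 10_000)]))
    query = _iv([(100, 150)], label="q")
    with pytest.warns(UserWarning, match="< 100"):
        association_test(query, [query], ws, n_randomizations=10, seed=0)


def test_depleted_subject_shows_fold_below_one():
    """A subject avoiding the query region mirrors the repressor observation."""
    ws = Workspace(_iv([(0, 50_000), (100_000, 150_000)]))
    # query sits exclusively in the first workspace block...
    query = _iv([(s, s + 50) for s in range(1000, 41_000, 2000)], label="G4")
    # ...while the subject densely tiles only the second block
    subject = _iv([(s, s + 400) for s in range(100_000, 150_000, 500)], label="repressor")
    (res,) = association_test(query, [subject], ws, n_randomizations=300, seed=4)
    assert res.observed == 0
    assert res.fold < 1.0
    assert res.p_deplete <= 1 / (300 + 1) * 2
    assert res.p_enrich > 0.5


# -- control sites -----------------------------------------------------------

def test_build_control_sites_enumeration():
    oq = _iv([(100, 140), (300, 340), (700, 740)], label="OQ")  # A, B, C
    promoters = _iv([(80, 400)])          # contains A and B
    dhs = Workspace(_iv([(0, 500)]))      # open chromatin over A and B
    g4 = _iv([(120, 130)])                # folded G4 on A
    ctrl = build_control_sites(oq, promoters, dhs, g4)
    assert [(iv.start, iv.end) for iv in ctrl] == [(300, 340)]


def test_build_control_sites_empty_warns():
    oq = _iv([(100, 140)], label="OQ")
    promoters = _iv([(5000, 6000)])
    dhs = Workspace(_iv([(0, 10_000)]))
    with pytest.warns(UserWarning):
        ctrl = build_control_sites(oq, promoters, dhs, IntervalSet([]))
    assert len(ctrl) == 0


def test_build_control_sites_matches_bruteforce(rng):
    from conftest import interval_mask
    oq = random_interval_set(rng, n=50, max_width=60, label="OQ")
    promoters = random_interval_set(rng, n=15, max_width=500)
    dhs_set = random_interval_set(rng, n=15, max_width=800)
    g4 = random_interval_set(rng, n=10, max_width=50)
    ctrl = build_control_sites(oq, promoters, Workspace(dhs_set), g4)
    pm, dm, gm = (interval_mask(x) for x in (promoters, dhs_set, g4))
    want = [
        (iv.start, iv.end)
        for iv in oq
        if pm[iv.start: iv.end].any() and dm[iv.start: iv.end].any()
        and not gm[iv.start: iv.end].any()
    ]
    assert sorted((iv.start, iv.end) for iv in ctrl) == sorted(want)


# -- Spearman & condition comparison ----------------------------------------

def test_spearman_extremes():
    x = [1.0, 2.0, 3.0, 4.0]
    assert spearman_rho(x, [10, 20, 30, 40]) == pytest.approx(1.0)
    assert spearman_rho(x, [8, 6, 4, 2]) == pytest.approx(-1.0)


def test_spearman_matches_scipy_with_ties(rng):
    x = rng.integers(0, 8, size=20).astype(float)  # many ties
    y = rng.normal(size=20)
    ours = spearman_rho(x, y)
    ref = stats.spearmanr(x, y).statistic
    assert ours == pytest.approx(ref, abs=1e-12)


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError):
        spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _mk_results(folds, query="q"):
    from g4hub.enrichment import EnrichmentResult
    return [
        EnrichmentResult(query, tf, 10 * f, 10.0, 1.0, f, 0.01, 0.99, 100, 50, 50)
        for tf, f in folds.items()
    ]


def test_compare_conditions_identical_inputs():
    res = _mk_results({"A": 2.0, "B": 5.0, "C": 1.0})
    cmp = compare_conditions(res, res)
    assert np.allclose(cmp.table["ratio"], 1.0)
    assert cmp.spearman == pytest.approx(1.0)


def test_compare_conditions_takes_max_over_replicates():
    res_a = _mk_results({"A": 2.0}) + _mk_results({"A": 7.0}) + _mk_results({"B": 3.0, "C": 1.0})
    res_b = _mk_results({"A": 1.0, "B": 3.0, "C": 1.0})
    cmp = compare_conditions(res_a, res_b)
    assert cmp.table.loc["A", "fold_a"] == 7.0
    assert cmp.n_ratio_above == 1  # only A has ratio >= 2


def test_compare_conditions_no_common_tfs():
    with pytest.raises(ValueError):
        compare_conditions(_mk_results({"A": 1.0}), _mk_results({"B": 1.0}))


def test_compare_conditions_noisy_monotone_map_approaches_one(rng):
    folds = {f"TF{i}": float(i + 1) for i in range(20)}
    noisy = {k: v + rng.normal(0, 1e-9) for k, v in folds.items()}
    cmp = compare_conditions(_mk_results(folds), _mk_results(noisy))
    assert cmp.spearman == pytest.approx(1.0)


def test_results_to_frame_columns():
    df = results_to_frame(_mk_results({"A": 2.0}))
    assert {"subject", "fold", "p_enrich", "p_deplete"} <= set(df.columns)
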
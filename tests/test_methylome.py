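"""M-value statistics: transform, variance filter, moderated test, classifier."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methaudit.methylome import (ClassifierThresholds, ProbeAnnotation,
                                 beta_to_m, bh_adjust, classify_probes,
                                 collapse_to_genes, m_to_beta,
                                 moderated_dm_test, per_probe_sd,
                                 variance_filter)
from oracles import brute_bh, brute_classify, brute_variance_filter


def _sheet(n_ctrl, n_trt):
    names = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_trt)]
    return names, pd.DataFrame(
        {"group": ["control"] * n_ctrl + ["treated"] * n_trt,
         "batch": [("a", "b")[i % 2] for i in range(n_ctrl + n_trt)]},
        index=pd.Index(names, name="sample"))


def _matrix(Y, names):
    return pd.DataFrame(Y, index=[f"p{i}" for i in range(Y.shape[0])],
                        columns=names)


# --- transform -------------------------------------------------------------

@pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
def test_logit2_reference_points(beta, m):
    assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)


def test_beta_outside_unit_interval_raises():
    with pytest.raises(ValueError):
        beta_to_m(1.2)


@given(st.floats(min_value=0.002, max_value=0.998))
@settings(max_examples=100, deadline=None)
def test_logit2_roundtrip_and_antisymmetry(b):
    assert m_to_beta(beta_to_m(b)) == pytest.approx(b, rel=1e-9)
    assert beta_to_m(b) == pytest.approx(-beta_to_m(1 - b), abs=1e-9)


def test_logit2_monotone():
    b = np.linspace(0.002, 0.998, 100)
    assert np.all(np.diff(beta_to_m(b)) > 0)


# --- variance filter -------------------------------------------------------

def test_constant_probe_never_kept():
    names, _ = _sheet(3, 3)
    rng = np.random.default_rng(0)
    Y = rng.normal(0, 1, (50, 6))
    Y[0] = 2.0  # constant probe
    vf = variance_filter(_matrix(Y, names))
    assert "p0" not in vf.kept_probe_ids


def test_identical_sds_keep_nothing():
    names, _ = _sheet(2, 2)
    # every probe an exact permutation of the same values -> equal SDs
    Y = np.array([[0.0, 1.0, 2.0, 3.0][::s] for s in (1, -1)] * 5)
    vf = variance_filter(_matrix(Y, names))
    assert vf.kept_probe_ids == []


def test_single_sample_errors():
    with pytest.raises(ValueError):
        per_probe_sd(pd.DataFrame({"s1": [0.1, 0.2]}))


def test_variance_filter_matches_oracle_with_spikes():
    rng = np.random.default_rng(42)
    Y = rng.normal(0, 0.5, (10_000, 6))
    Y[:30] *= 6.0  # spiked high-variance probes
    names, _ = _sheet(3, 3)
    m = _matrix(Y, names)
    vf = variance_filter(m, multiplier=2.5)
    expected = brute_variance_filter(Y, 2.5)
    assert set(vf.kept_probe_ids) == {f"p{i}" for i in np.nonzero(expected)[0]}
    assert {f"p{i}" for i in range(30)} <= set(vf.kept_probe_ids)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=200, deadline=None)
def test_variance_filter_oracle_property(seed):
    rng = np.random.default_rng(seed)
    G = int(rng.integers(5, 60))
    n = int(rng.integers(2, 8))
    Y = rng.normal(0, rng.uniform(0.1, 2.0, (G, 1)), (G, n))
    names = [f"s{i}" for i in range(n)]
    vf = variance_filter(_matrix(Y, names), multiplier=float(rng.uniform(0, 3)))
    thr = vf.threshold
    expected = {f"p{i}" for i in range(G)
                if np.std(Y[i], ddof=1) > thr}
    assert set(vf.kept_probe_ids) == expected


# --- moderated test --------------------------------------------------------

def test_d0_zero_equals_classical_t():
    rng = np.random.default_rng(1)
    names, sheet = _sheet(4, 4)
    Y = rng.normal(0, 1, (200, 8))
    m = _matrix(Y, names)
    res = moderated_dm_test(m, sheet, d0_override=0)
    from scipy import stats as ss
    t_classic, p_classic = ss.ttest_ind(Y[:, 4:], Y[:, :4], axis=1)
    np.testing.assert_allclose(res["t"].to_numpy(), t_classic, atol=1e-10)
    np.testing.assert_allclose(res["p"].to_numpy(), p_classic, atol=1e-10)


def test_equal_group_means_give_zero_effect():
    names, sheet = _sheet(3, 3)
    Y = np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0],
                  [0.0, 1.0, -1.0, -1.0, 1.0, 0.0]])
    res = moderated_dm_test(_matrix(Y, names), sheet)
    assert res["effect"].abs().max() < 1e-12
    assert res["t"].abs().max() < 1e-12
    np.testing.assert_allclose(res["p"].to_numpy(), 1.0, atol=1e-9)


def test_full_shrinkage_limit_uses_pooled_variance():
    rng = np.random.default_rng(3)
    names, sheet = _sheet(3, 3)
    Y = rng.normal(0, 0.5, (500, 6))
    res = moderated_dm_test(_matrix(Y, names), sheet, d0_override=np.inf)
    # all probes share one posterior variance -> t proportional to effect
    ratio = res["t"] / res["effect"]
    assert np.allclose(ratio, ratio.iloc[0], rtol=1e-9)


def test_hyperparameter_recovery_and_type1():
    """2000 null probes at n=3 vs 3: s0^2 within 15% of the generating
    variance and raw-p type-I error at 0.05 inside [0.03, 0.07]."""
    rng = np.random.default_rng(2024)
    names, sheet = _sheet(3, 3)
    sigma2 = 0.25
    Y = rng.normal(0, np.sqrt(sigma2), (2000, 6))
    res = moderated_dm_test(_matrix(Y, names), sheet)
    assert abs(res.attrs["s0sq"] - sigma2) / sigma2 < 0.15
    rate = float((res["p"] < 0.05).mean())
    assert 0.03 <= rate <= 0.07


def test_batch_covariate_absorbs_batch_shift():
    rng = np.random.default_rng(9)
    names, sheet = _sheet(4, 4)
    Y = rng.normal(0, 0.3, (300, 8))
    shift = (sheet["batch"] == "b").to_numpy(dtype=float) * 5.0
    Yb = Y + shift
    res = moderated_dm_test(_matrix(Yb, names), sheet, include_batch=True)
    ref = moderated_dm_test(_matrix(Y, names), sheet, include_batch=True)
    np.testing.assert_allclose(res["effect"], ref["effect"], atol=1e-9)


def test_too_few_samples_errors():
    names, sheet = _sheet(1, 3)
    with pytest.raises(ValueError, match="2 samples per group"):
        moderated_dm_test(_matrix(np.zeros((3, 4)), names), sheet)


def test_moderated_test_matches_limma(tmp_path):
    """Independent oracle: R limma lmFit+eBayes on the same matrix must give
    the same prior df, prior variance, moderated t and p."""
    rng = np.random.default_rng(42)
    G, n = 300, 3
    s = np.sqrt(rng.chisquare(6, G) / 6) * 0.5
    Y = rng.normal(0, s[:, None], (G, 2 * n))
    Y[:10, n:] += 2.0
    names, sheet = _sheet(n, n)
    m = _matrix(Y, names)
    res = moderated_dm_test(m, sheet)
    m.to_csv(tmp_path / "m.tsv", sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
        design <- cbind(1, c(rep(0,{n}), rep(1,{n})))
        fit <- eBayes(lmFit(m, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
        cat(fit$df.prior, fit$s2.prior, "\\n")
    """)
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                          text=True, timeout=300)
    assert proc.returncode == 0, proc.stderr
    d0_r, s0sq_r = map(float, proc.stdout.split())
    lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    assert res.attrs["d0"] == pytest.approx(d0_r, rel=1e-6)
    assert res.attrs["s0sq"] == pytest.approx(s0sq_r, rel=1e-6)
    np.testing.assert_allclose(res["t"], lim["t"], atol=1e-8)
    np.testing.assert_allclose(res["p"], lim["p"], atol=1e-8)


# --- BH --------------------------------------------------------------------

def test_bh_single_p_unchanged():
    assert bh_adjust([0.04])[0] == pytest.approx(0.04)


def test_bh_stepup_arithmetic():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])


def test_bh_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=1000)
    np.testing.assert_allclose(bh_adjust(p), brute_bh(p), atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
@settings(max_examples=200, deadline=None)
def test_bh_oracle_property(ps):
    p = np.array(ps)
    adj = bh_adjust(p)
    np.testing.assert_allclose(adj, brute_bh(p), atol=1e-12)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)


# --- classifier ------------------------------------------------------------

def _classified_fixture(seed=0, G=400, n=3, planted=3):
    rng = np.random.default_rng(seed)
    names, sheet = _sheet(n, n)
    base = np.where(rng.random(G) < 0.7, -3.0, 3.0)
    Y = base[:, None] + rng.normal(0, 0.5, (G, 2 * n))
    Y[:planted, :n] = -3.0 + rng.normal(0, 0.3, (planted, n))
    Y[:planted, n:] = 0.0 + rng.normal(0, 0.3, (planted, n))
    m = _matrix(Y, names)
    ann = [ProbeAnnotation(f"p{i}", "chr1", 100 * i,
                           gene=("MGMT" if i < planted else f"g{i % 50}"),
                           cpg_island=bool(i < planted or rng.random() < 0.3))
           for i in range(G)]
    return m, sheet, ann


def test_classifier_flags_match_oracle():
    m, sheet, ann = _classified_fixture()
    dm = moderated_dm_test(m, sheet)
    flags = classify_probes(dm, m, sheet, ann)
    sds = per_probe_sd(m).to_numpy()
    groups = sheet["group"]
    ctrl = m.loc[:, (groups == "control").to_numpy()].mean(axis=1).to_numpy()
    trt = m.loc[:, (groups == "treated").to_numpy()].mean(axis=1).to_numpy()
    expected = brute_classify(dm["p_adj"].to_numpy(),
                              [a.cpg_island for a in ann],
                              dm["effect"].to_numpy(), ctrl, trt, sds)
    np.testing.assert_array_equal(flags["candidate"].to_numpy(), expected)


def test_single_criterion_failure_is_visible():
    m, sheet, ann = _classified_fixture()
    # flip the island flag of a planted probe: exactly one criterion fails
    ann[0] = ProbeAnnotation("p0", "chr1", 0, gene="MGMT", cpg_island=False)
    dm = moderated_dm_test(m, sheet)
    flags = classify_probes(dm, m, sheet, ann)
    row = flags.loc["p0"]
    assert not row["candidate"] and not row["crit_island"]
    assert row[["crit_p_adj", "crit_delta_m", "crit_control_m",
                "crit_treated_m"]].all()


def test_boundary_control_mean_is_excluded():
    names, sheet = _sheet(3, 3)
    Y = np.array([[-1.0, -1.0, -1.0, 5.0, 5.0, 5.0]])
    Y = np.vstack([Y, np.random.default_rng(0).normal(0, 1, (20, 6))])
    m = _matrix(Y, names)
    dm = moderated_dm_test(m, sheet)
    ann = [ProbeAnnotation(f"p{i}", "chr1", i, gene="x", cpg_island=True)
           for i in range(len(m))]
    flags = classify_probes(dm, m, sheet, ann)
    assert not flags.loc["p0", "crit_control_m"]  # strict inequality at -1
    assert not flags.loc["p0", "candidate"]


def test_missing_annotation_raises():
    m, sheet, ann = _classified_fixture(G=10)
    dm = moderated_dm_test(m, sheet)
    with pytest.raises(KeyError):
        classify_probes(dm, m, sheet, ann[:-1])


def test_classifier_invariant_to_orderings():
    m, sheet, ann = _classified_fixture(seed=5)
    dm = moderated_dm_test(m, sheet)
    ref = classify_probes(dm, m, sheet, ann)["candidate"]
    perm = np.random.default_rng(1).permutation(len(m))
    m2 = m.iloc[perm]
    dm2 = moderated_dm_test(m2, sheet)
    out2 = classify_probes(dm2, m2, sheet, ann)["candidate"]
    pd.testing.assert_series_equal(ref.sort_index(), out2.sort_index())
    # sample order within groups
    cols = list(m.columns)
    cols[0], cols[1] = cols[1], cols[0]
    m3 = m[cols]
    dm3 = moderated_dm_test(m3, sheet)
    out3 = classify_probes(dm3, m3, sheet, ann)["candidate"]
    pd.testing.assert_series_equal(ref, out3)


# --- gene collapse ---------------------------------------------------------

def _mini_classified(rows):
    df = pd.DataFrame(rows).set_index("probe_id")
    return df


def test_three_probes_one_gene():
    rows = [{"probe_id": f"p{i}", "candidate": True, "direction": "hyper",
             "p_adj": 0.01} for i in range(3)]
    ann = [ProbeAnnotation(f"p{i}", "c", i, gene="MGMT", cpg_island=True)
           for i in range(3)]
    genes = collapse_to_genes(_mini_classified(rows), ann)
    assert list(genes.index) == ["MGMT"]
    assert genes.loc["MGMT", "n_probes"] == 3


def test_empty_gene_label_reported_as_intergenic():
    rows = [{"probe_id": "p0", "candidate": True, "direction": "hyper",
             "p_adj": 0.01}]
    ann = [ProbeAnnotation("p0", "c", 0, gene="", cpg_island=True)]
    genes = collapse_to_genes(_mini_classified(rows), ann)
    assert list(genes.index) == ["intergenic"]


def test_gene_count_matches_distinct_labels():
    rng = np.random.default_rng(11)
    rows, ann = [], []
    for i in range(200):
        gene = f"g{rng.integers(40)}"
        rows.append({"probe_id": f"p{i}", "candidate": bool(rng.random() < 0.5),
                     "direction": "hyper" if rng.random() < 0.5 else "hypo",
                     "p_adj": float(rng.random())})
        ann.append(ProbeAnnotation(f"p{i}", "c", i, gene=gene, cpg_island=True))
    genes = collapse_to_genes(_mini_classified(rows), ann)
    expected = {a.gene for a, r in zip(ann, rows) if r["candidate"]}
    assert set(genes.index) == expected
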
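"""Slide-effect removal, PCA QC, DE counting, gene-set selection, clustering."""

import numpy as np
import pandas as pd
import pytest

from polyqtc.expression import (
    DEThresholds,
    build_design,
    cluster_profiles,
    count_de_timecourse,
    fit_models,
    moderate_and_test,
    pca_qc,
    remove_slide_effect,
    select_early_response,
    select_hd_specific,
)
from polyqtc.simdata import ArraySimConfig, gen_array_data


@pytest.fixture(scope="module")
def meta():
    cfg = ArraySimConfig(n_genes=2, seed=0)
    long, _ = gen_array_data(cfg)
    return (
        long[["array_id", "slide_id", "cellline", "time_h", "replicate"]]
        .drop_duplicates("array_id")
        .set_index("array_id")
    )


def _expr_with_slides(meta, slide_offsets, cond_effects=None, noise_sd=0.0,
                      n_genes=40, seed=0):
    rng = np.random.default_rng(seed)
    cond_effects = cond_effects or {}
    cond = [f"{r.cellline}_{r.time_h:g}" for r in meta.itertuples()]
    base = np.array([cond_effects.get(c, 0.0) for c in cond])
    slide = meta["slide_id"].map(slide_offsets).fillna(0.0).to_numpy()
    y = np.tile(base + slide, (n_genes, 1)) + rng.normal(0, noise_sd, (n_genes, len(meta)))
    return pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)], columns=meta.index)


class TestRemoveSlideEffect:
    def test_no_slide_effect_is_a_near_identity(self, meta):
        expr = _expr_with_slides(meta, {}, noise_sd=0.1, seed=1)
        out = remove_slide_effect(expr, meta)
        assert np.abs(out.to_numpy() - expr.to_numpy()).max() < 0.15

    def test_planted_offsets_removed(self, meta):
        offsets = {"s0": 1.0, "s1": -1.0}
        expr = _expr_with_slides(meta, offsets, noise_sd=0.05, seed=2)
        out = remove_slide_effect(expr, meta)
        # after removal, per-slide means agree across slides within 0.05
        arr_means = out.mean(axis=0)
        per_slide = arr_means.groupby(meta["slide_id"]).mean()
        assert per_slide.max() - per_slide.min() < 0.05

    def test_condition_contrasts_preserved(self, meta):
        """Removing slide effects must leave the planted condition structure
        intact: corrected condition means equal the planted effects up to a
        single global constant."""
        offsets = {"s0": 0.8, "s2": -0.5}
        cond_effects = {"HD_72": 1.0, "C_48": -0.6}
        expr = _expr_with_slides(meta, offsets, cond_effects, noise_sd=0.05, seed=3)
        out = remove_slide_effect(expr, meta)
        cond = pd.Series(
            [f"{r.cellline}_{r.time_h:g}" for r in meta.itertuples()], index=meta.index
        )
        gene_means = out.mean(axis=0)
        cond_means = gene_means.groupby(cond.values).mean()
        recovered = {c: cond_means[c] - cond_means["C_0"] for c in ("HD_72", "C_48")}
        assert recovered["HD_72"] == pytest.approx(1.0, abs=0.05)
        assert recovered["C_48"] == pytest.approx(-0.6, abs=0.05)

    def test_confounded_slide_raises(self, meta):
        confounded = meta.copy()
        confounded["slide_id"] = [
            f"s{r.cellline}_{r.time_h:g}" for r in confounded.itertuples()
        ]
        expr = _expr_with_slides(meta, {}, n_genes=5)
        expr.columns = confounded.index
        with pytest.raises(ValueError, match="confounded|aliased"):
            remove_slide_effect(expr, confounded)


class TestPCA:
    def test_single_direction_of_variation_dominates_pc1(self, meta):
        rng = np.random.default_rng(4)
        direction = rng.normal(size=30)
        weights = rng.normal(size=len(meta))
        y = np.outer(direction, weights)
        expr = pd.DataFrame(y, index=[f"g{i}" for i in range(30)], columns=meta.index)
        _, explained = pca_qc(expr)
        assert explained[0] > 0.999

    def test_cell_lines_separate_on_pc1_when_planted(self, meta):
        sep = (meta["cellline"] == "HD").astype(float).to_numpy()
        rng = np.random.default_rng(5)
        y = np.outer(rng.normal(1.0, 0.1, 50), sep) + rng.normal(0, 0.05, (50, len(meta)))
        expr = pd.DataFrame(y, index=[f"g{i}" for i in range(50)], columns=meta.index)
        scores, _ = pca_qc(expr, meta)
        hd = scores.loc[meta["cellline"] == "HD", "PC1"]
        c = scores.loc[meta["cellline"] == "C", "PC1"]
        assert (hd.min() > c.max()) or (c.min() > hd.max())

    def test_explained_variance_sums_to_one(self, meta):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            rng.normal(size=(20, len(meta))),
            index=[f"g{i}" for i in range(20)],
            columns=meta.index,
        )
        x = expr.to_numpy().T
        x = x - x.mean(axis=0)
        s = np.linalg.svd(x, compute_uv=False)
        _, explained = pca_qc(expr)
        assert np.sum(s**2 / (s**2).sum()) == pytest.approx(1.0)
        assert np.all(explained <= 1.0)


@pytest.fixture(scope="module")
def planted_result(meta):
    cond_effects = {f"HD_{t:g}": 2.0 for t in (36.0, 48.0, 72.0, 96.0, 120.0)}
    rng = np.random.default_rng(7)
    cond = [f"{r.cellline}_{r.time_h:g}" for r in meta.itertuples()]
    base = np.array([cond_effects.get(c, 0.0) for c in cond])
    n_genes, n_de = 300, 100
    y = rng.normal(0, 0.2, (n_genes, len(meta)))
    y[:n_de] += base
    expr = pd.DataFrame(y, index=[f"g{i:03d}" for i in range(n_genes)], columns=meta.index)
    fit = fit_models(expr, build_design(meta))
    return moderate_and_test(fit), n_genes, n_de


class TestSelectionsAndCounts:
    def test_planted_up_genes_counted_at_their_time(self, planted_result):
        res, n_genes, n_de = planted_result
        counts = count_de_timecourse(res)
        dd72 = counts[(counts.family == "DD") & (counts.time_h == 72.0)].iloc[0]
        assert dd72.n_up >= 0.95 * n_de
        assert dd72.n_down <= 5

    def test_counts_bounded_by_gene_number(self, planted_result):
        res, n_genes, _ = planted_result
        counts = count_de_timecourse(res)
        assert ((counts.n_up + counts.n_down) <= n_genes).all()

    def test_hd_specific_selection_recovers_planted_genes(self, planted_result):
        res, _, n_de = planted_result
        selected = select_hd_specific(res)
        planted = {f"g{i:03d}" for i in range(n_de)}
        assert len(selected & planted) / n_de >= 0.95

    def test_early_selection_requires_all_three_timepoints(self):
        # hand-built result tables: g1 significant at all of 4/8/24 h,
        # g2 only at 4 and 8 h
        rows = []
        for t in (4.0, 8.0, 24.0):
            rows.append({"gene_id": "g1", "time_h": t, "logFC": 1, "t": 5, "p": 0.01, "adj_p": 0.05})
            p2 = 0.01 if t < 24 else 0.5
            rows.append({"gene_id": "g2", "time_h": t, "logFC": 1, "t": 2, "p": p2, "adj_p": 0.6})
        from polyqtc.expression.linmod import ContrastResult

        res = ContrastResult(
            per_timepoint={"DD": pd.DataFrame(rows)},
            overall=pd.DataFrame({"gene_id": ["g1", "g2"], "F": [0, 0], "p": [1, 1], "adj_p": [1, 1]}),
            d0=np.inf, s02=1.0, df_resid=10,
            s2=pd.Series([1.0, 1.0]), s2_post=pd.Series([1.0, 1.0]),
        )
        assert select_early_response(res) == {"g1"}
        empty = ContrastResult(
            per_timepoint={"DD": pd.DataFrame(columns=["gene_id", "time_h", "logFC", "t", "p", "adj_p"])},
            overall=pd.DataFrame(columns=["gene_id", "F", "p", "adj_p"]),
            d0=np.inf, s02=1.0, df_resid=10, s2=pd.Series(dtype=float), s2_post=pd.Series(dtype=float),
        )
        assert select_early_response(empty) == set()


class TestClusterProfiles:
    def _expr_two_families(self, meta, seed=8):
        rng = np.random.default_rng(seed)
        times = sorted(meta["time_h"].unique())
        t_arr = meta["time_h"].to_numpy()
        up = (t_arr / 120.0)
        down = -up
        rows = []
        names = []
        for i in range(20):
            rows.append(up + rng.normal(0, 0.05, len(meta)))
            names.append(f"up{i:02d}")
        for i in range(20):
            rows.append(down + rng.normal(0, 0.05, len(meta)))
            names.append(f"dn{i:02d}")
        return pd.DataFrame(rows, index=names, columns=meta.index)

    def test_two_planted_families_recovered_with_high_purity(self, meta):
        expr = self._expr_two_families(meta)
        labels, summary = cluster_profiles(expr, meta, set(expr.index), n_clusters=2)
        up_labels = labels[[g for g in labels.index if g.startswith("up")]]
        dn_labels = labels[[g for g in labels.index if g.startswith("dn")]]
        purity = max(
            (up_labels == 1).mean() + (dn_labels == 2).mean(),
            (up_labels == 2).mean() + (dn_labels == 1).mean(),
        ) / 2
        assert purity >= 0.95

    def test_profiles_standardized(self, meta):
        expr = self._expr_two_families(meta)
        labels, summary = cluster_profiles(expr, meta, set(expr.index), n_clusters=2)
        # cluster means of standardized profiles: per-gene mean 0, sd 1 holds
        # before averaging; check the cluster-level profile is bounded
        for c, sub in summary.groupby("cluster"):
            assert abs(sub["mean"].mean()) < 0.2

    def test_labels_invariant_to_gene_order(self, meta):
        expr = self._expr_two_families(meta)
        genes = list(expr.index)
        labels1, _ = cluster_profiles(expr, meta, genes, n_clusters=2)
        labels2, _ = cluster_profiles(expr.iloc[::-1], meta, genes[::-1], n_clusters=2)
        assert labels1.sort_index().equals(labels2.sort_index())

    def test_too_few_genes_rejected(self, meta):
        expr = self._expr_two_families(meta)
        with pytest.raises(ValueError, match="2 genes"):
            cluster_profiles(expr, meta, {"up00"}, n_clusters=2)
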
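"""End-to-end demonstration pipeline on synthetic data.

Generates three tissue sections (7 / 11 / 17 PCW analogs) and three
organoids interpolating the 11- and 17-PCW references, runs every analysis
stage, and writes a machine-readable JSON report that asserts the
pipeline's core correctness properties (oracle equivalences, contracts,
recovery checks) at demonstration scale.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    io_core,
    lineage,
    maturation_path,
    module_scores,
    niche_similarity,
    pseudobulk,
    spatial_stats,
    synthetic_data,
)
from ._exceptions import DegenerateInputError

logger = logging.getLogger("mbstage.demo")

DEMO_ALPHAS = (0.25, 0.5, 0.75)


def _brute_force_pair_counts(grid, labeling):
    """Independent edge enumeration used as the in-report oracle."""
    label_of = dict(zip(labeling.spots, labeling.labels))
    counts: dict[tuple[str, str], int] = {}
    for a, b in grid.adjacency:
        la, lb = label_of[a], label_of[b]
        if niche_similarity.UNASSIGNED in (la, lb):
            continue
        key = tuple(sorted((la, lb)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _profile_as_dict(profile):
    basis = profile.pair_basis()
    iu = np.triu_indices(len(profile.types))
    return {
        tuple(sorted(p)): int(c)
        for p, c in zip(basis, profile.pair_counts[iu])
        if c > 0
    }


def _rook_grid_2x2():
    return io_core.SpotGrid(
        spots=["s0", "s1", "s2", "s3"],
        array_coords=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        phys_coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        adjacency={("s0", "s1"), ("s0", "s2"), ("s1", "s3"), ("s2", "s3")},
    )


def run_demo(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Run every pipeline stage on synthetic data; return the report dict."""
    report: dict = {"seed": seed, "checks": {}, "results": {}}
    checks = report["checks"]
    results = report["results"]

    cfg = synthetic_data.SyntheticConfig(seed=seed, grid_radius=5, n_genes=120, n_cells=800)
    rng = cfg.rng()

    # --- spatial samples -------------------------------------------------
    tissues = []
    for meta in cfg.timepoints:
        grid, ab, cm, gt = synthetic_data.generate_tissue_sample(cfg, meta, rng=rng)
        niche_similarity.build_adjacency(grid)
        tissues.append((grid, ab, cm, gt))
    ref_a = next(t[3] for t in tissues if t[3].meta.timepoint_value == 11.0)
    ref_b = next(t[3] for t in tissues if t[3].meta.timepoint_value == 17.0)
    organoids = []
    for alpha in DEMO_ALPHAS:
        grid, ab, cm, gt = synthetic_data.generate_organoid_sample(
            cfg, ref_a, ref_b, mix_alpha=alpha, rng=rng
        )
        niche_similarity.build_adjacency(grid)
        organoids.append((grid, ab, cm, gt))

    # --- labeling, pair profiles, oracle equivalence ----------------------
    profiles, ids, oracle_ok = [], [], True
    for grid, ab, cm, gt in tissues + organoids:
        labeling = niche_similarity.label_spots(ab)
        profile = niche_similarity.count_neighbor_pairs(grid, labeling)
        oracle_ok &= _profile_as_dict(profile) == _brute_force_pair_counts(grid, labeling)
        oracle_ok &= profile.n_edges == len(grid.adjacency)  # no unassigned here
        profiles.append(profile)
        ids.append(grid.meta.sample_id)
    checks["pair_counts_match_bruteforce"] = bool(oracle_ok)

    # --- similarity contract ----------------------------------------------
    sim = niche_similarity.sample_similarity(profiles, ids)
    S, off = sim.S, ~np.eye(len(ids), dtype=bool)
    checks["similarity_contract"] = bool(
        np.allclose(S, S.T)
        and np.allclose(np.diag(S), 1.0)
        and S.min() >= 0.0
        and S.max() <= 1.0
        and np.isclose(S[off].min(), 0.0)
    )

    # --- temporal alignment -----------------------------------------------
    tissue_metas = [t[0].meta for t in tissues]
    estimates = []
    for (grid, *_), alpha in zip(organoids, DEMO_ALPHAS):
        ta = niche_similarity.temporal_alignment(sim, grid.meta.sample_id, tissue_metas)
        estimates.append(ta.estimated_timepoint)
        results[f"alignment_pcw_alpha_{alpha}"] = round(ta.estimated_timepoint, 3)
    # single-seed run: assert the rank trend (strict monotonicity of the
    # mean estimate over seeds is asserted in the test suite)
    from scipy.stats import spearmanr

    checks["alignment_increases_with_alpha"] = bool(
        spearmanr(DEMO_ALPHAS, estimates).statistic > 0
    )

    # --- maturation path: moving average + trend --------------------------
    grid0, ab0, cm0, gt0 = tissues[1]
    io_core.lognormalize(cm0)
    y0, y1 = grid0.phys_coords[:, 1].min(), grid0.phys_coords[:, 1].max()
    poly = np.array([[0.0, y0], [0.0, y1]])
    path = maturation_path.order_spots_on_polyline(grid0, poly, radius=1.2)
    mod_gene = cfg.module_spec[0].genes[0]
    expr = cm0.dense_layer("lognorm")[:, cm0.genes.index(mod_gene)]
    path_idx = [grid0.index_of(s) for s in path]
    smoothed = maturation_path.moving_average(expr[path_idx], window=min(50, len(path)))
    rho, p_trend = maturation_path.path_trend_test(expr[path_idx], n_perm=499, seed=seed)
    results["path_trend_rho"] = round(float(rho), 3)
    results["path_trend_p"] = round(float(p_trend), 4)
    ma_oracle = maturation_path.moving_average([1, 2, 3, 4, 5], 3)
    checks["moving_average_oracle"] = bool(
        np.allclose(ma_oracle, [1.5, 2, 3, 4, 4.5])
        and np.allclose(maturation_path.moving_average([1, 2, 3], 9), 2.0)
        and smoothed.min() >= expr[path_idx].min() - 1e-12
        and smoothed.max() <= expr[path_idx].max() + 1e-12
    )

    # --- Moran's I ---------------------------------------------------------
    rook = _rook_grid_2x2()
    checker = synthetic_data.generate_field(rook, "checkerboard")
    m_res = spatial_stats.morans_i(rook, checker, method="exact")
    constant_raises = False
    try:
        spatial_stats.morans_i(grid0, synthetic_data.generate_field(grid0, "constant"))
    except DegenerateInputError:
        constant_raises = True
    checks["moran_checkerboard_is_minus_one"] = bool(np.isclose(m_res.I, -1.0))
    checks["moran_constant_raises"] = constant_raises
    results["moran_checkerboard_I"] = round(float(m_res.I), 6)

    lig = synthetic_data.generate_field(grid0, "smooth_gradient")
    rec = synthetic_data.generate_field(grid0, "smooth_gradient")
    noise = synthetic_data.generate_field(grid0, "iid_noise", seed=seed + 1)
    score_grad = spatial_stats.neighbor_lr_score(grid0, lig, rec)
    score_noise = spatial_stats.neighbor_lr_score(grid0, noise, noise)
    ranked = spatial_stats.rank_pairs_by_moran(
        grid0, {"grad_pair": score_grad, "noise_pair": score_noise}, n_perm=199, seed=seed
    )
    results["top_moran_pair"] = str(ranked.iloc[0]["pair"])
    results["top_moran_I"] = round(float(ranked.iloc[0]["I"]), 3)

    # --- permutation / rank-sum exactness ----------------------------------
    df_small = pd.DataFrame({"m": [0.0, 0.0, 1.0, 1.0]})
    res_small = module_scores.resampled_permutation_test(
        df_small, np.array([True, True, False, False]),
        np.array([False, False, True, True]), n_perm=999, seed=seed,
    )[0]
    checks["perm_test_exhaustive_small_case"] = bool(np.isclose(res_small.mean_p, 3 / 7))
    checks["ranksum_exact_small_case"] = bool(
        np.isclose(module_scores.ranksum_compare([1, 2], [3, 4]), 1 / 3)
        and np.isclose(module_scores.ranksum_compare([1.0, 2.0], [1.0, 2.0]), 1.0)
    )

    # --- single-cell stages -------------------------------------------------
    cm_sc, meta_sc, gt_sc = synthetic_data.generate_single_cell_dataset(cfg, rng=rng)
    io_core.lognormalize(cm_sc)
    hvg = lineage.select_hvg(cm_sc, meta_sc, n_hvg=60)
    toy = lineage.HVGSelection(
        per_replicate={
            ("t1", "r1"): ["a", "b", "c"],
            ("t1", "r2"): ["b", "c", "d"],
            ("t2", "r1"): ["c", "e"],
        }
    )
    checks["hvg_intersect_union_identity"] = toy.final == ["b", "c", "e"]

    from sklearn.decomposition import PCA

    gmask = [cm_sc.genes.index(g) for g in hvg.final]
    X = cm_sc.dense_layer("lognorm")[:, gmask]
    emb = PCA(n_components=5, svd_solver="full").fit_transform(X - X.mean(axis=0))
    cell_graph = lineage.build_knn_graph(emb, k=10)
    cg = lineage.cluster_connectivity(cell_graph, list(meta_sc["cluster"]))
    clusters_sorted = sorted(cg.clusters)
    lp = lineage.prune_and_path(cg, root=clusters_sorted[0], endpoint=clusters_sorted[-1])
    results["lineage_path"] = lp.clusters
    boundary = lineage.ClusterGraph(
        clusters={"a": 1, "b": 1, "c": 1},
        edges={("a", "b"): 0.05, ("b", "c"): 0.049},
    )
    pruned = boundary.pruned()
    checks["prune_boundary_strict"] = bool(
        pruned.has_edge("a", "b") and not pruned.has_edge("b", "c")
    )

    pt, adj_r2 = lineage.pc1_pseudotime(
        cm_sc, hvg, meta_sc["cell_type"], root_type=cfg.sc_cell_types[0]
    )
    from scipy.stats import spearmanr

    rho_pt = abs(spearmanr(pt, gt_sc.pseudotime).statistic)
    results["pseudotime_recovery_spearman"] = round(float(rho_pt), 3)
    results["pseudotime_adjusted_r2"] = round(float(adj_r2), 3)
    checks["pseudotime_recovery"] = bool(rho_pt >= 0.9)

    profiles_bins = lineage.bin_profiles(
        pt, cm_sc, [m.genes[0] for m in cfg.module_spec], n_perm=999, seed=seed
    )
    results["bin_calls"] = {p.gene: p.start_end_call for p in profiles_bins}

    # --- module scores ------------------------------------------------------
    mods = [module_scores.GeneModule(m.module_id, m.genes) for m in cfg.module_spec]
    score_table = module_scores.activation_score(cm_sc, mods, groups=meta_sc)
    early = (meta_sc["timepoint"] == cfg.sc_timepoints[0]).to_numpy()
    late = (meta_sc["timepoint"] == cfg.sc_timepoints[-1]).to_numpy()
    perm_results = module_scores.resampled_permutation_test(
        score_table, early, late, n_perm=499, n_resample=10, seed=seed
    )
    results["module_mean_p"] = {r.module_id: round(r.mean_p, 4) for r in perm_results}
    stats_df, xgrid, dens = module_scores.timepoint_profile(
        score_table.column(mods[0].module_id),
        meta_sc.rename(columns={"model": "dataset"}),
    )
    integrals = [float(np.trapezoid(d, xgrid)) for d in dens.values()]
    checks["density_normalized"] = bool(np.allclose(integrals, 1.0, atol=1e-3))
    results["ranksum_p_early_late"] = float(
        module_scores.ranksum_compare(pt[early], pt[late])
    )

    # --- pseudobulk ---------------------------------------------------------
    group_labels = [
        f"{m}_{t:g}" for m, t in zip(meta_sc["model"], meta_sc["timepoint"])
    ]
    pb = pseudobulk.pseudobulk_means(cm_sc, group_labels, hvg.final)
    corr = pseudobulk.correlation_matrix(pb)
    results["pseudobulk_min_r"] = round(float(corr.to_numpy().min()), 3)
    ident = pseudobulk.PseudobulkTable(
        groups=["g1", "g2", "g3"],
        genes=["x", "y", "z"],
        means=np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]]),
        n_cells=[1, 1, 1],
    )
    cfix = pseudobulk.correlation_matrix(ident)
    checks["pseudobulk_fixtures"] = bool(
        np.isclose(cfix.loc["g1", "g2"], 1.0) and np.isclose(cfix.loc["g1", "g3"], -1.0)
    )

    report["all_checks_pass"] = all(checks.values())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_core.write_table(sim.as_frame().reset_index(), outdir / "similarity.tsv")
        io_core.write_table(module_scores.results_frame(perm_results), outdir / "module_tests.tsv")
        io_core.write_table(corr.reset_index(), outdir / "pseudobulk_correlation.tsv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        logger.info("demo report written to %s", outdir / "report.json")
    return report
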
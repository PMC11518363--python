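"""Reusable validation experiments over the full pipeline.

These drive the power/calibration analyses: Cq-recovery accuracy of the SDM
caller over a parameter grid, nominal-p calibration of the permutation test
under a label-free null, and planted-set recovery through the entire
curve-to-enrichment pipeline. The analysis drivers and the acceptance
machinery all call these, so reported numbers always come from the same
code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import enrichment_score, normalize_and_test, permutation_null
from .qpcr import call_cq_sdm, call_cq_table, interplate_calibrate, normalize_delta_cq
from .ranking import RankedList, rank_differential
from .synthetic_data import (
    CurveParams,
    PanelLayout,
    PlantedSet,
    SimulationConfig,
    make_default_layout,
    simulate_curve,
    simulate_experiment,
)


def cq_recovery_grid(
    k_values: np.ndarray | None = None,
    m_values: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_cycles: int = 45,
    seed: int = 0,
) -> pd.DataFrame:
    """Called vs true SDM Cq for noiseless (by default) logistic curves.

    The default grid spans slopes k in [0.5, 2] and true Cq in [15, 33];
    the closed form of the simulator guarantees the true SDM cycle, so the
    error column measures the caller alone.
    """
    if k_values is None:
        k_values = np.linspace(0.5, 2.0, 7)
    if m_values is None:
        m_values = np.linspace(15.0, 33.0, 10)
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_values:
        for true_cq in m_values:
            params = CurveParams(slope=float(k), noise_sd=noise_sd)
            curve = simulate_curve(float(true_cq), params, rng, n_cycles=n_cycles)
            called = call_cq_sdm(curve)
            rows.append(
                {
                    "slope_k": float(k),
                    "true_cq": float(true_cq),
                    "called_cq": called,
                    "abs_error": abs(called - true_cq),
                }
            )
    return pd.DataFrame(rows)


def null_pvalue_calibration(
    N: int = 372,
    G_values: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    B: int = 1000,
    n_replicates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Nominal p-values of random sets against random rankings.

    Under the label-free null the observed set is exchangeable with the
    permutation null, so each replicate draws a random G-subset of a ranked
    universe of size N, scores it, and tests it against a fresh B-sample
    null. The returned p-values should be (super-)uniform.
    """
    names = [f"m{i:04d}" for i in range(N)]
    ranked = RankedList(names=names, scores=np.arange(N, 0, -1.0))
    rng = np.random.default_rng(seed)
    rows = []
    for G in G_values:
        for rep in range(n_replicates):
            members = rng.choice(names, size=G, replace=False)
            es = enrichment_score(ranked, set(members)).es
            null = permutation_null(ranked, G, B=B, rng=rng, exhaustive="never")
            _, p = normalize_and_test(es, null)
            rows.append({"G": G, "replicate": rep, "p_nominal": p})
    return pd.DataFrame(rows)


def planted_recovery_experiment(
    n_runs: int = 100,
    base_seed: int = 0,
    G: int = 5,
    delta: float = 2.0,
    noise_sd: float = 0.1,
    n_samples_per_condition: int = 3,
    n_null_sets: int = 5,
    B: int = 1000,
    layout: PanelLayout | None = None,
) -> pd.DataFrame:
    """Planted-set detection through the full curve-to-enrichment pipeline.

    Each run simulates the 384-well panel with one planted up-regulated
    G-member set (effect size ``delta`` Cq cycles, fluorescence noise SD
    ``noise_sd``), pushes raw curves through Cq calling, interplate
    calibration, delta-Cq normalization and ranking, and records the nominal
    enrichment p of the planted set plus ``n_null_sets`` random non-planted
    sets of the same size. Detection means p <= 0.05.
    """
    if layout is None:
        layout = make_default_layout()
    mirnas = layout.mirna_assays
    rows = []
    for run in range(n_runs):
        seed = int(base_seed + run) % (2**31 - 1)
        rng = np.random.default_rng(seed)
        planted = tuple(rng.choice(mirnas, size=G, replace=False))
        cfg = SimulationConfig(
            n_samples_per_condition=n_samples_per_condition,
            n_de_mirnas=0,
            de_effect_size=delta,
            curve_params=CurveParams(noise_sd=noise_sd),
            planted_sets=(PlantedSet("planted", planted, "up"),),
            seed=seed,
        )
        exp = simulate_experiment(layout, cfg)
        cq = interplate_calibrate(call_cq_table(exp.curves))
        matrix = normalize_delta_cq(cq, exp.conditions)
        ranked = rank_differential(matrix)
        universe = set(ranked.names)
        null = permutation_null(ranked, G, B=B, rng=rng, exhaustive="never")

        es = enrichment_score(ranked, set(planted) & universe).es
        _, p = normalize_and_test(es, null)
        rows.append({"run": run, "set_type": "planted", "es": es, "p_nominal": p})

        others = [m for m in mirnas if m not in planted and m in universe]
        for j in range(n_null_sets):
            members = rng.choice(others, size=G, replace=False)
            es_j = enrichment_score(ranked, set(members)).es
            _, p_j = normalize_and_test(es_j, null)
            rows.append({"run": run, "set_type": "null", "es": es_j, "p_nominal": p_j})
    return pd.DataFrame(rows)


def recovery_rates(recovery: pd.DataFrame, alpha: float = 0.05) -> dict[str, float]:
    """Detection rate of planted sets and false-positive rate of null sets."""
    out = {}
    for set_type, grp in recovery.groupby("set_type"):
        out[set_type] = float((grp["p_nominal"] <= alpha).mean())
    return {"detection_rate": out.get("planted", float("nan")),
            "false_positive_rate": out.get("null", float("nan"))}
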
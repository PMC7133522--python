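"""Seeded end-to-end evaluations of the pipeline on synthetic studies.

Each function regenerates its inputs from scratch under the given seed,
runs the relevant stage(s), and returns the measured quantity: planted
tau_D recovery and permutation power, null calibration of the permutation
p-values, response-ratio sign recovery, and context (in)dependence of the
cross-location merge. These back both the test suite and the
reproducibility script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .consentrait import find_consensus_clades, permutation_test, tau_d
from .crossloc import context_dependence, merged_tree, widespread_otus
from .datatypes import ResponseSet
from .pipeline import consentrait_on_subtree, run_multilocation
from .ratios import log2_response_ratios, size_factors
from .synthetic import (
    plant_conserved_responses,
    simulate_counts,
    simulate_multilocation,
    simulate_tree,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def planted_recovery(
    target_depth: float,
    n_seeds: int = 20,
    n_tips: int = 128,
    fidelity: float = 1.0,
    n_randomizations: int = 1000,
    seed: int = 0,
    with_power: bool = True,
) -> dict:
    """Recover planted tau_D at full fidelity and measure permutation power.

    Returns the maximum relative error of recovered tau_D per direction
    against the mean planted depth of that direction, and the fraction of
    runs where both directions' permutation p-values are <= 0.05.
    """
    seeds = _spawn_seeds(seed, n_seeds)
    rel_errors: list[float] = []
    detected = 0
    for s in seeds:
        tree = simulate_tree(n_tips, seed=s)
        resp, truth = plant_conserved_responses(
            tree, target_depth, fidelity, seed=s + 1
        )
        clades = find_consensus_clades(tree, resp)
        for d in "+-":
            planted = [c.genetic_depth for c in truth.planted_clades
                       if c.direction == d]
            recovered = tau_d(clades, d)
            if planted and recovered is not None:
                mean_planted = float(np.mean(planted))
                rel_errors.append(
                    abs(recovered - mean_planted) / mean_planted
                )
        if with_power:
            res = permutation_test(
                tree, resp, n_randomizations=n_randomizations, seed=s + 2
            )
            ok = (res.p_pos is None or res.p_pos <= 0.05) and (
                res.p_neg is None or res.p_neg <= 0.05
            )
            detected += ok
    return {
        "max_rel_error": float(max(rel_errors)),
        "power": detected / n_seeds if with_power else None,
        "n_seeds": n_seeds,
    }


def null_calibration(
    n_runs: int = 200,
    n_tips: int = 64,
    n_randomizations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the permutation test under i.i.d. random directions."""
    seeds = _spawn_seeds(seed, n_runs)
    hits = 0
    for s in seeds:
        tree = simulate_tree(n_tips, seed=s)
        rng = np.random.default_rng(s + 1)
        signs = rng.choice([-1.0, 1.0], size=n_tips)
        resp = ResponseSet(pd.Series(signs, index=tree.tip_labels))
        res = permutation_test(
            tree, resp, n_randomizations=n_randomizations, seed=s + 2
        )
        hits += res.p_pos is not None and res.p_pos <= alpha
    return {"fraction_significant": hits / n_runs, "n_runs": n_runs}


def sign_recovery(
    n_otus: int = 300,
    effect: float = 1.0,
    dispersion: float = 0.1,
    n_plots: int = 10,
    seed: int = 0,
) -> dict:
    """Fraction of OTUs whose estimated direction matches the planted sign."""
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n_otus)
    lfc = pd.Series(signs * effect, index=[f"t{i}" for i in range(n_otus)])
    table = simulate_counts(
        ResponseSet(lfc, "x"), n_control=n_plots, n_treatment=n_plots,
        dispersion=dispersion, seed=seed + 1,
    )
    est = log2_response_ratios(table, size_factors(table))
    truth_dir = np.where(signs > 0, "+", "-")
    return {
        "agreement": float((est.direction.to_numpy() == truth_dir).mean()),
        "n_otus": n_otus,
    }


def context_delta(
    n_seeds: int = 20,
    n_tips: int = 128,
    target_depth: float = 0.03,
    n_locations: int = 4,
    occupancy_prob: float = 0.8,
    seed: int = 0,
) -> dict:
    """Context dependence of the cross-location merge under shared truth.

    Two measurement paths per seed: the planted (fidelity-1.0) direction
    vectors restricted by each location's occupancy — isolating what the
    merge itself does to tau_D — and the full count-estimation path, where
    per-location direction errors additionally shallow the per-location
    tau_D. Reports |delta| / mean individual tau_D for both.
    """
    seeds = _spawn_seeds(seed, n_seeds)
    truth_fracs: list[float] = []
    estimated_fracs: list[float] = []
    n_excluded_locations = 0
    for s in seeds:
        tree = simulate_tree(n_tips, seed=s)
        _, truth = plant_conserved_responses(tree, target_depth, 1.0,
                                             seed=s + 1)
        tables = simulate_multilocation(
            tree, truth, n_locations=n_locations,
            occupancy_prob=occupancy_prob, seed=s + 2,
        )
        # planted-direction path; a location where one direction is
        # engulfed (e.g. >90% of its present OTUs respond one way, so the
        # whole subtree is one consensus clade) has no tau_D for the
        # minority direction and is excluded, as the statistic is
        # undefined there
        per, resps = [], []
        for table in tables:
            r = ResponseSet(truth.true_log2fc.loc[table.otu_ids],
                            table.location)
            resps.append(r)
            result = consentrait_on_subtree(tree, r)
            if result.tau_pos is None or result.tau_neg is None:
                n_excluded_locations += 1
            else:
                per.append(result)
        merged_resp = widespread_otus(resps)
        merged = consentrait_on_subtree(
            merged_tree(tree, merged_resp.otu_ids), merged_resp
        )
        if not per or merged.tau_pos is None or merged.tau_neg is None:
            continue
        cd = context_dependence(per, merged)
        truth_fracs.append(abs(cd.delta) / cd.mean_individual_tau)
        # full estimation path
        try:
            res = run_multilocation(tree, tables, seed=s + 3)
        except Exception:
            continue
        estimated_fracs.append(
            abs(res.context.delta) / res.context.mean_individual_tau
        )
    return {
        "max_abs_delta_fraction": float(max(truth_fracs)),
        "mean_abs_delta_fraction": float(np.mean(truth_fracs)),
        "estimated_path_mean_fraction": float(np.mean(estimated_fracs)),
        "n_seeds": n_seeds,
        "n_excluded_locations": n_excluded_locations,
    }
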
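"""Canonical validation experiments for the CSMA analysis pipeline.

Each function builds its own synthetic inputs at the reference study
conditions (array geometry, cell counts, noise levels, library size), runs
the package end to end, and returns the measured quantities.  They are the
backbone of the acceptance checks and are convenient entry points for
exploring the pipeline's operating characteristics.

Problem sizes are chosen to make each experiment conclusive yet quick: the
screen-scale experiments use the full 984-sample / 50-control sub-array, the
per-cell experiments use a few tens of thousands of cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cytometry import classify_cell_cycle, gate_phenotypes, knockdown_efficacy
from .imaging import measure_cells, segment_nuclei
from .layout import CONTROL_ID, ArrayLayout, SampleSheet, assign_samples, build_layout
from .pipeline import estimate_null_index_sd, score_arrays
from .screenstats import rank_product
from .simgen import (
    SpotTruth,
    ki67_scale_for_index_shift,
    latent_sd_for_correlation,
    null_effects,
    planted_shift_for_z,
    render_spot_image,
    simulate_screen,
    simulate_spot_cells,
    truth_to_records,
)


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % 2**31)


def gpcr_screen_layout(seed: int = 11) -> ArrayLayout:
    """The reference screening sub-array: 108 x 36 spots at 500 um pitch,
    200 um spots, 16 pins, 492 genes x 2 constructs + 5% negative controls."""
    lay = build_layout(108, 36, pitch_um=500, diameter_um=200, n_wells=1, n_pins=16)
    sheet = SampleSheet.from_gene_list([f"GPCR{i:03d}" for i in range(492)], 2)
    return assign_samples(lay, sheet, control_fraction=0.05, seed=seed)


def knockdown_recovery(
    planted_pct: tuple[float, ...] = (30.0, 60.0, 90.0),
    n_spots: int = 25,
    n_seeds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Recover planted silencing levels with the cytoplasmic-ring estimator.

    For each planted level, ``n_seeds`` independent experiments of
    ``n_spots`` treated + ``n_spots`` control replicate spots (~51 cells
    each, default noise, full transfection) are simulated in table mode and
    the per-cell median estimator applied.  Returns one row per (level, run)
    with the estimate and its error in percentage points.
    """
    rows = []
    for pct in planted_pct:
        for run in range(n_seeds):
            rng = np.random.default_rng(_child_seed(seed, int(pct), run))
            treated, control = [], []
            for i in range(n_spots):
                tt = SpotTruth(spot_id=i, knockdown_frac=pct / 100.0, transfection_frac=1.0)
                treated.append(
                    truth_to_records(simulate_spot_cells(tt, rng, enforce_spacing=False), tt)
                )
                tc = SpotTruth(spot_id=1000 + i, knockdown_frac=0.0, transfection_frac=0.0)
                control.append(
                    truth_to_records(simulate_spot_cells(tc, rng, enforce_spacing=False), tc)
                )
            res = knockdown_efficacy(
                pd.concat(treated, ignore_index=True),
                pd.concat(control, ignore_index=True),
                n_boot=200,
                seed=_child_seed(seed, int(pct), run, 7),
            )
            rows.append(
                {
                    "planted_pct": pct,
                    "run": run,
                    "estimate_pct": res.efficacy_pct,
                    "error_points": res.efficacy_pct - pct,
                }
            )
    return pd.DataFrame(rows)


def cycle_recovery(
    planted: tuple[float, float, float] = (0.60, 0.30, 0.10),
    n_cells: int = 2000,
    seed: int = 0,
) -> dict:
    """Recover planted cell-cycle fractions from integrated-DAPI gating."""
    tt = SpotTruth(
        mean_cells=n_cells,
        sd_cells=0,
        cycle_probs=planted,
        apoptosis_frac=0.0,
        spot_diameter_um=2000,
    )
    cells = truth_to_records(
        simulate_spot_cells(tt, _child_seed(seed, 1), enforce_spacing=False), tt
    )
    res = classify_cell_cycle(cells)
    doubled = cells.copy()
    doubled["dapi_mean"] *= 2.0
    res2 = classify_cell_cycle(doubled)
    return {
        "fractions": res.fractions,
        "planted": dict(zip(("G1S", "G2", "M"), planted)),
        "errors_points": {
            k: 100.0 * (res.fractions[k] - p) for k, p in zip(("G1S", "G2", "M"), planted)
        },
        "scale_invariant": res.fractions == res2.fractions,
    }


def apoptosis_recovery(planted_frac: float = 0.20, n_cells: int = 1000, seed: int = 0) -> dict:
    """Recover a planted apoptotic fraction with control-anchored cPARP gating."""
    ta = SpotTruth(mean_cells=n_cells, sd_cells=0, apoptosis_frac=planted_frac, spot_diameter_um=2000)
    tc = SpotTruth(mean_cells=n_cells, sd_cells=0, apoptosis_frac=0.0, spot_diameter_um=2000)
    treated = truth_to_records(simulate_spot_cells(ta, _child_seed(seed, 1), enforce_spacing=False), ta)
    control = truth_to_records(simulate_spot_cells(tc, _child_seed(seed, 2), enforce_spacing=False), tc)
    res = gate_phenotypes(treated, control_cells=control)
    null = gate_phenotypes(control, control_cells=control)
    return {
        "cparp_pos_frac": float((res.label == "cparp_pos").mean()),
        "planted_frac": planted_frac,
        "null_cparp_pos_frac": float((null.label == "cparp_pos").mean()),
    }


def null_screen_calibration(seed: int = 0, layout: ArrayLayout | None = None) -> dict:
    """z-score calibration of a 984-sample null screen (one array).

    Returns the fraction of |z| >= 2 among samples alongside the exact
    binomial 99% band around the Gaussian expectation 2 * Phi(-2) = 4.55%.
    """
    lay = layout or gpcr_screen_layout()
    ids = sorted({s.sample_id for s in lay.occupied() if s.sample_id != CONTROL_ID})
    sim = simulate_screen(lay, null_effects(ids), n_replicates=1, seed=_child_seed(seed, 3))
    z = score_arrays(sim.cells)["z"].iloc[:, 0]
    n = int(z.notna().sum())
    p_expected = 2.0 * stats.norm.cdf(-2.0)
    lo = stats.binom.ppf(0.005, n, p_expected) / n
    hi = stats.binom.ppf(0.995, n, p_expected) / n
    frac = float((z.abs() >= 2).mean())
    return {"frac_abs_z_ge_2": frac, "band": (float(lo), float(hi)), "n_samples": n}


def rank_product_null_uniformity(
    n_samples: int = 500, n_conditions: int = 3, n_perm: int = 10000, seed: int = 0
) -> dict:
    """KS uniformity of rank-product permutation p-values under the null."""
    rng = np.random.default_rng(_child_seed(seed, 4))
    scores = pd.DataFrame(
        rng.normal(size=(n_samples, n_conditions)),
        columns=[f"cond_{j}" for j in range(n_conditions)],
    )
    rp = rank_product(scores, n_perm=n_perm, seed=_child_seed(seed, 5))
    ks = stats.kstest(rp["rp_p"], "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue)}


def planted_hit_power(
    n_hits: int = 20,
    z_effect: float = -3.0,
    n_replicates: int = 2,
    threshold: float = 2.0,
    n_screens: int = 20,
    n_pilots: int = 20,
    seed: int = 0,
) -> dict:
    """Recall and false-hit rate for planted growth-inhibitory siRNAs.

    ``n_hits`` samples of the 984-sample screen receive a Ki-67 suppression
    whose expected post-standardization z equals ``z_effect`` (the planting
    accounts for the contamination of the array mean/s.d. by the hits and for
    the apoptotic Ki-67 floor; the null index s.d. is calibrated on
    ``n_pilots`` pilot arrays).  ``n_screens`` independent screens of
    ``n_replicates`` arrays are scored with the |z| >= ``threshold`` rule;
    recall is reported as the mean over screens, the false-hit rate over all
    null samples.
    """
    lay = gpcr_screen_layout()
    ids = sorted({s.sample_id for s in lay.occupied() if s.sample_id != CONTROL_ID})
    sigma0 = estimate_null_index_sd(lay, n_pilots=n_pilots, seed=_child_seed(seed, 6))
    shift_sd = planted_shift_for_z(z_effect, len(ids), n_hits)
    scale = ki67_scale_for_index_shift(shift_sd * sigma0)

    recalls, false_rates = [], []
    for s in range(n_screens):
        rng = np.random.default_rng(_child_seed(seed, 7, s))
        hits = list(rng.choice(ids, n_hits, replace=False))
        eff = null_effects(ids)
        eff.loc[hits, "ki67_scale"] = scale
        sim = simulate_screen(
            lay, eff, n_replicates=n_replicates, seed=_child_seed(seed, 8, s)
        )
        res = score_arrays(sim.cells, threshold=threshold)["results"]
        called = set(res[res["hit"] == "inhibitory"].index)
        recalls.append(len(called & set(hits)) / n_hits)
        false_rates.append(len(called - set(hits)) / (len(ids) - n_hits))
    return {
        "recall": float(np.mean(recalls)),
        "recall_per_screen": recalls,
        "false_hit_rate": float(np.mean(false_rates)),
        "ki67_scale": float(scale),
        "null_index_sd": float(sigma0),
    }


def replicate_concordance_experiment(
    target_r: float = 0.8, n_pilots: int = 8, seed: int = 0
) -> dict:
    """Plant a between-replicate concordance and measure the Pearson r.

    Per-sample latent log2 Ki-67 effects shared by both replicate arrays are
    drawn with the s.d. that sets the expected between-replicate correlation
    of spot indices to ``target_r`` given the measured null index s.d.
    """
    lay = gpcr_screen_layout()
    sigma0 = estimate_null_index_sd(lay, n_pilots=n_pilots, seed=_child_seed(seed, 9))
    ids = sorted({s.sample_id for s in lay.occupied() if s.sample_id != CONTROL_ID})
    sd = latent_sd_for_correlation(target_r, sigma0)
    sim = simulate_screen(
        lay,
        null_effects(ids),
        n_replicates=2,
        sample_effect_sd=sd,
        seed=_child_seed(seed, 10),
    )
    out = score_arrays(sim.cells)
    return {"pearson_r": float(out["concordance_r"]), "target_r": target_r}


def segmentation_roundtrip(n_spots: int = 50, seed: int = 0) -> dict:
    """Render spots at default noise, re-segment, and score count recovery.

    A detection matches a true nucleus when their centroids are within one
    mean nuclear diameter (10 um); recall and precision are pooled over all
    spots.
    """
    from scipy.spatial import cKDTree

    n_truth = n_det = n_match = 0
    for s in range(n_spots):
        tt = SpotTruth(spot_id=s)
        cells = simulate_spot_cells(tt, _child_seed(seed, 11, s), enforce_spacing=True)
        img = render_spot_image(cells, seed=_child_seed(seed, 12, s), spot_id=s)
        mask = segment_nuclei(img.channels["dapi"], pixel_size_um=img.pixel_size_um)
        rec = measure_cells(mask, img)
        n_truth += len(cells)
        n_det += len(rec)
        if len(rec) and len(cells):
            tree = cKDTree(rec[["x_um", "y_um"]].to_numpy())
            d, _ = tree.query(cells[["x_um", "y_um"]].to_numpy())
            n_match += int((d < 10.0).sum())
    return {
        "recall": n_match / n_truth if n_truth else float("nan"),
        "precision": n_match / n_det if n_det else float("nan"),
        "n_true_cells": n_truth,
        "n_detected": n_det,
    }
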
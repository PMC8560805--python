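"""Self-contained validation benchmarks.

Each function regenerates its synthetic inputs from a seed, runs the
relevant slice of the pipeline, and returns plain numbers.  They back
both the acceptance test suite and ``scripts/acceptance.py``; problem
sizes are chosen so the full battery runs in a few minutes on one CPU
(documented in the methods note).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cohort import bland_altman, ellipses_overlap, fit_cohort_model, leave_one_out_assignment
from .config import RunConfig
from .detect import merge_axoneme, segment_cilia, segment_nuclei, detect_basal_bodies
from .morphometry import skeleton_length
from .pipeline import analyze_field, fit_length_calibration
from .reference import reference_lines, sample_cohort_medians
from .summarize import bootstrap_median, ciliogenesis
from .synth import SyntheticSpec, match_to_truth, render_field


def table_group_mean_ciliogenesis() -> dict[str, float]:
    """Mean of the published per-line ciliogenesis percentages per
    cohort group (controls, ATD, CED)."""
    df = reference_lines()
    out = {}
    for group in ("control", "ATD", "CED"):
        vals = df.loc[df["group"] == group, "ciliogenesis_pct"]
        out[group] = float(vals.mean())
    return out


def length_recovery(seed: int = 0, n_target: int = 150) -> dict[str, float]:
    """Calibrated-length recovery on cilia with arc lengths uniform in
    2-5 µm under noise and staining gaps; the calibration is fitted on a
    separate artificial dataset (different seed stream)."""
    config = RunConfig()
    cal = fit_length_calibration(n_fields=6, seed=seed + 90000, config=config)
    spec = SyntheticSpec(
        n_cells=12, frac_ciliated=1.0, frac_spot=0.0,
        length_dist=("uniform", (2.0, 5.0)),
        noise_gaussian_sd=0.02, gap_prob=0.5, seed=seed,
    )
    errs: list[float] = []
    j = 0
    while len(errs) < n_target and j < 3 * (n_target // spec.n_cells + 1):
        img, truth = render_field(replace(spec, seed=seed + j))
        j += 1
        cands = segment_cilia(merge_axoneme(img, config.detection),
                              img.pixel_size_um, config.detection)
        matches = match_to_truth([c.endpoints for c in cands], truth,
                                 img.pixel_size_um)
        tb = {c.cell_id: c for c in truth.cells}
        for k, cid in matches.items():
            corrected = float(cal.apply(
                skeleton_length(cands[k], img.pixel_size_um)))
            t = tb[cid].true_length_um
            errs.append(abs(corrected - t) / t)
    return {
        "median_abs_rel_err_pct": float(100 * np.median(errs)),
        "n_cilia": len(errs),
        "calibration_slope": cal.slope,
        "calibration_offset_um": cal.offset,
    }


def counting_exactness(seed: int = 0, n_fields: int = 20) -> dict[str, float]:
    """Noise-free fields: nucleus / cilium-candidate / basal-body counts
    vs ground truth, field by field."""
    config = RunConfig()
    exact = 0
    for j in range(n_fields):
        spec = SyntheticSpec(n_cells=12, frac_ciliated=1.0, frac_spot=0.0,
                             noise_gaussian_sd=0.0, seed=seed + j)
        img, truth = render_field(spec)
        n_true = len(truth.of_class("cilium"))
        ok = (
            segment_nuclei(img, config.detection).count == truth.n_nuclei
            and len(segment_cilia(merge_axoneme(img, config.detection),
                                  img.pixel_size_um, config.detection)) == n_true
            and len(detect_basal_bodies(img, config.detection)) == n_true
        )
        exact += bool(ok)
    return {"n_exact_fields": exact, "n_fields": n_fields}


def ciliogenesis_recovery(seed: int = 0, n_cells_target: int = 500,
                          frac_ciliated: float = 0.90) -> dict[str, float]:
    """Measured ciliogenesis on a simulated line with a known ciliated
    fraction, analyzed field by field through the full pipeline."""
    spec = SyntheticSpec(frac_ciliated=frac_ciliated, frac_spot=0.07,
                         seed=seed)
    per_field = []
    n = 0
    j = 0
    while n < n_cells_target:
        img, _ = render_field(replace(spec, seed=seed + j))
        j += 1
        res = analyze_field(img)
        per_field.append(res.cell_classes)
        n += res.n_nuclei
    cg = ciliogenesis(per_field)
    return {
        "measured_pct": cg.pct_cilium,
        "true_pct": 100 * frac_ciliated,
        "n_cells": cg.n_cells,
    }


def ift_recovery(seed: int = 0, n_replicates: int = 10,
                 n_fields_per_condition: int = 2) -> dict[str, float]:
    """Median IFT88 area under healthy-like (0.43 µm²) and CED-like
    (0.82 µm²) accumulation settings, with per-replicate ordering."""
    conditions = {
        "healthy": dict(true_area=0.43, length=("normal", (3.71, 0.55))),
        "ced": dict(true_area=0.82, length=("normal", (2.44, 0.45))),
    }
    medians: dict[str, list[float]] = {k: [] for k in conditions}
    for rep in range(n_replicates):
        for name, c in conditions.items():
            vals: list[float] = []
            for j in range(n_fields_per_condition):
                spec = SyntheticSpec(
                    n_cells=12, frac_ciliated=1.0, frac_spot=0.0,
                    ift_area_dist=("constant", (c["true_area"],)),
                    length_dist=c["length"],
                    seed=seed + 1000 * rep + 100 * (name == "ced") + j,
                )
                img, _ = render_field(spec)
                res = analyze_field(img)
                vals += [r.ift_area_um2 for r in res.records
                         if r.ift_area_um2 > 0]
            medians[name].append(float(np.median(vals)))
    ordered = sum(c > h for h, c in zip(medians["healthy"], medians["ced"]))
    return {
        "healthy_median_um2": float(np.median(medians["healthy"])),
        "ced_median_um2": float(np.median(medians["ced"])),
        "true_healthy_um2": 0.43,
        "true_ced_um2": 0.82,
        "n_replicates_ced_exceeds_healthy": int(ordered),
        "n_replicates": n_replicates,
    }


def agreement_coverage(seed: int = 0, n: int = 200) -> dict[str, float]:
    """Fraction of Normal(0, σ) paired differences inside the
    Bland-Altman mean ± 2 SD band (population value ≈ 95.4%)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.3, n)
    b = np.zeros(n)
    res = bland_altman(a, b)
    frac = float(np.mean((res.differences >= res.loa_low)
                         & (res.differences <= res.loa_high)))
    return {"coverage_pct": 100 * frac, "n_pairs": n}


def bootstrap_sd_check(seed: int = 0, n: int = 200,
                       n_boot: int = 10000) -> dict[str, float]:
    """Bootstrap SD of the median on one Exponential sample vs the SD of
    medians over fresh samples of the same size (brute-force oracle)."""
    rng = np.random.default_rng(seed)
    x = rng.exponential(1.0, n)
    _, sd_boot = bootstrap_median(x, n_boot=n_boot, seed=seed + 1)
    fresh = np.median(rng.exponential(1.0, (n_boot, n)), axis=1)
    sd_fresh = float(fresh.std(ddof=1))
    return {"sd_boot": sd_boot, "sd_fresh": sd_fresh,
            "ratio": sd_boot / sd_fresh, "n": n}


def cluster_recovery(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Cohorts sampled at the published group centroids and printed SDs:
    ATD/CED 0.9-ellipse separation and leave-one-out recovery."""
    n_overlap = 0
    min_correct = 14
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        groups = sample_cohort_medians({"control": 6, "ATD": 5, "CED": 3}, rng)
        model = fit_cohort_model(groups)
        n_overlap += ellipses_overlap(model, "ATD", "CED", 0.9)
        correct, _total = leave_one_out_assignment(groups)
        min_correct = min(min_correct, correct)
    return {
        "n_atd_ced_overlaps": n_overlap,
        "min_loo_correct": min_correct,
        "n_lines": 14,
        "n_seeds": n_seeds,
    }
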
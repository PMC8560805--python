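"""Packaged reference data: the healthy cilium phenotype and the
published per-line phenotype tables of the control and skeletal-
ciliopathy cohorts (ATD = asphyxiating thoracic dystrophy, CED =
cranioectodermal dysplasia, plus one CED-like and one SRPS line).

These are laboratory-specific standards shipped as guidance; every
loader accepts an override path so each lab can substitute values
refitted on its own control lines.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Cohort centroids in the (median length µm, median IFT88 area µm²)
#: plane, as published for the three separable groups.
GROUP_CENTROIDS: dict[str, tuple[float, float]] = {
    "control": (3.71, 0.43),
    "ATD": (4.81, 0.54),
    "CED": (2.44, 0.82),
}

#: Published group-level ciliogenesis (%, mean ± SD across lines).
GROUP_CILIOGENESIS: dict[str, tuple[float, float]] = {
    "control": (90.0, 8.0),
    "ATD": (93.0, 6.0),
    "CED": (80.0, 14.0),
}

#: Published group-row SDs of the (length µm, IFT µm²) medians — the
#: scale at which the group medians themselves are uncertain.
GROUP_MEDIAN_SD: dict[str, dict[str, float]] = {
    "control": {"length_sd": 0.039, "ift_sd": 0.01},
    "ATD": {"length_sd": 0.06, "ift_sd": 0.03},
    "CED": {"length_sd": 0.05, "ift_sd": 0.03},
}


def _data_path(name: str) -> Path:
    return Path(resources.files("cilioscope").joinpath("data", name))


def healthy_reference(path: str | Path | None = None) -> dict:
    """The healthy cilium phenotype triplet with SDs.

    Returns ``{"ciliogenesis_pct": {"value", "sd"}, "length_um": ...,
    "ift_um2": ...}``.
    """
    p = Path(path) if path else _data_path("healthy_reference.json")
    ref = json.loads(p.read_text())
    for key in ("ciliogenesis_pct", "length_um", "ift_um2"):
        if key not in ref:
            raise ValueError(f"reference file {p} missing key {key!r}")
    return ref


def reference_lines(path: str | Path | None = None) -> pd.DataFrame:
    """Per-line published phenotypes (6 controls + 10 patients)."""
    p = Path(path) if path else _data_path("reference_lines.csv")
    return pd.read_csv(p)


def group_spreads(lines: pd.DataFrame | None = None) -> dict[str, dict[str, float]]:
    """Between-line SDs of median length and IFT area per cohort group,
    computed from the published per-line table.  These set the spread of
    simulated cohorts so synthetic lines scatter like the real ones."""
    df = lines if lines is not None else reference_lines()
    out: dict[str, dict[str, float]] = {}
    for group, sub in df.groupby("group"):
        if len(sub) < 2:
            continue
        out[group] = {
            "length_sd": float(sub["length_um"].std(ddof=1)),
            "ift_sd": float(sub["ift_um2"].std(ddof=1)),
        }
    return out


def sample_cohort_medians(
    n_lines: dict[str, int],
    rng: np.random.Generator,
    centroids: dict[str, tuple[float, float]] | None = None,
    spreads: dict[str, dict[str, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Draw per-line (length, IFT) medians for each cohort group from
    independent normals at the group centroid.  The default spread is
    the published group-row SD (:data:`GROUP_MEDIAN_SD`); pass
    :func:`group_spreads` for the larger empirical between-line scatter.
    Used for clustering benchmarks that operate at the statistics layer
    (no image rendering)."""
    centroids = centroids or GROUP_CENTROIDS
    spreads = spreads or GROUP_MEDIAN_SD
    out = {}
    for group, n in n_lines.items():
        cx, cy = centroids[group]
        sx = spreads[group]["length_sd"]
        sy = spreads[group]["ift_sd"]
        pts = np.column_stack(
            [rng.normal(cx, sx, n), np.clip(rng.normal(cy, sy, n), 0.01, None)]
        )
        out[group] = pts
    return out
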
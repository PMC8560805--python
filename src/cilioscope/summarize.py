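"""Per-line phenotype summaries.

A cell line's cilium phenotype is a triplet: ciliogenesis (% of cells
with an extended axoneme, with spot / unciliated fractions alongside),
the bootstrap median cilium length (µm), and the bootstrap median IFT88
accumulation area (µm²).  Medians are summarized by bootstrap because
per-cilium lengths and areas are not normally distributed; the point
estimate is the plain sample median (resampling-free) and the bootstrap
contributes only its SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import BootstrapConfig
from .morphometry import CiliumRecord

CLASSES = ("cilium", "spot", "none")


@dataclass
class CiliogenesisResult:
    pct_cilium: float
    pct_spot: float
    pct_none: float
    sd_over_fields: float
    n_cells: int


@dataclass
class LineSummary:
    """Three-parameter cilium phenotype of one cell line."""

    line_id: str
    n_cells: int
    ciliogenesis_pct: float
    ciliogenesis_sd: float  # across per-field percentages
    pct_spot: float
    pct_none: float
    length_median_um: float  # nan when no ciliated cells
    length_sd_boot: float
    ift_median_um2: float
    ift_sd_boot: float
    n_cilia_length: int
    n_cilia_ift: int


def ciliogenesis(per_field_classes: Sequence[Sequence[str]]) -> CiliogenesisResult:
    """Pooled cilium / spot / none percentages over all cells, with the
    SD of the ciliated percentage across fields."""
    fields = [list(f) for f in per_field_classes if len(f) > 0]
    all_cells = [c for f in fields for c in f]
    if not all_cells:
        raise ValueError("ciliogenesis requires at least one cell")
    bad = set(all_cells) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown cell class(es): {sorted(bad)}")
    n = len(all_cells)
    pct = {c: 100.0 * all_cells.count(c) / n for c in CLASSES}
    per_field = [100.0 * f.count("cilium") / len(f) for f in fields]
    sd = float(np.std(per_field, ddof=1)) if len(per_field) > 1 else 0.0
    return CiliogenesisResult(pct["cilium"], pct["spot"], pct["none"], sd, n)


def bootstrap_median(values: Sequence[float], n_boot: int = 10000,
                     seed: int = 20210527) -> tuple[float, float]:
    """Sample median with its bootstrap SD.

    The median is the plain sample median (independent of seed and
    ``n_boot``); the SD is the standard deviation of medians over
    ``n_boot`` full-size resamples with replacement.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError(f"bootstrap_median needs >= 2 values, got {x.size}")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    meds = np.median(x[idx], axis=1)
    return float(np.median(x)), float(meds.std(ddof=1))


def summarize_line(
    line_id: str,
    per_field_classes: Sequence[Sequence[str]],
    records: Iterable[CiliumRecord],
    bootstrap: BootstrapConfig | None = None,
) -> LineSummary:
    """Assemble the per-line phenotype from per-cell classes and
    per-cilium records.  Length and IFT medians use class-"cilium"
    records only; zero-area IFT records (no accumulation detected or no
    transport plane) are excluded from the IFT median."""
    bootstrap = bootstrap or BootstrapConfig()
    cil = ciliogenesis(per_field_classes)
    recs = [r for r in records if r.structure_class == "cilium"]
    lengths = [r.length_um for r in recs]
    areas = [r.ift_area_um2 for r in recs if r.ift_area_um2 > 0]

    if len(lengths) >= 2:
        lmed, lsd = bootstrap_median(lengths, bootstrap.n_boot, bootstrap.seed)
    else:
        lmed, lsd = float("nan"), float("nan")
    if len(areas) >= 2:
        amed, asd = bootstrap_median(areas, bootstrap.n_boot, bootstrap.seed + 1)
    else:
        amed, asd = float("nan"), float("nan")

    return LineSummary(
        line_id=line_id,
        n_cells=cil.n_cells,
        ciliogenesis_pct=cil.pct_cilium,
        ciliogenesis_sd=cil.sd_over_fields,
        pct_spot=cil.pct_spot,
        pct_none=cil.pct_none,
        length_median_um=lmed,
        length_sd_boot=lsd,
        ift_median_um2=amed,
        ift_sd_boot=asd,
        n_cilia_length=len(lengths),
        n_cilia_ift=len(areas),
    )


def summaries_to_frame(summaries: Iterable[LineSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def normalize_to_controls(
    values: Mapping[str, float], control_line_ids: Sequence[str]
) -> dict[str, float]:
    """Divide each per-line value by the mean over the control lines, so
    normalized controls average exactly 1.  Idempotent."""
    controls = [values[c] for c in control_line_ids if c in values]
    if not controls:
        raise ValueError("no control lines found among the values")
    mean = float(np.mean(controls))
    if mean <= 0:
        raise ValueError(f"control mean must be > 0, got {mean}")
    return {k: v / mean for k, v in values.items()}


def aggregate_group_mean(summaries: Sequence[LineSummary]) -> dict[str, float]:
    """Group row as the mean of per-line values (one of the two
    aggregation conventions; the pooled-bootstrap alternative is
    :func:`pooled_group_median`)."""
    if not summaries:
        raise ValueError("empty group")
    return {
        "ciliogenesis_pct": float(np.mean([s.ciliogenesis_pct for s in summaries])),
        "length_median_um": float(np.nanmean([s.length_median_um for s in summaries])),
        "ift_median_um2": float(np.nanmean([s.ift_median_um2 for s in summaries])),
        "n_lines": len(summaries),
    }


def pooled_group_median(values_per_line: Mapping[str, Sequence[float]],
                        n_boot: int = 10000, seed: int = 20210527
                        ) -> tuple[float, float]:
    """Group median over all cilia pooled across the group's lines."""
    pooled = [v for vals in values_per_line.values() for v in vals]
    return bootstrap_median(pooled, n_boot=n_boot, seed=seed)
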
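"""Method agreement and cohort clustering.

Two validation tools — Bland–Altman limits of agreement and the paired
two-sided t-test — compare automated measurements against a second
method (e.g. manual scoring).  The clustering layer models each cohort
group (control, ATD, CED) as a bivariate normal over per-line medians
in the (cilium length, IFT88 area) plane; groups are drawn as
chi-square confidence ellipses at the 0.5 and 0.9 levels and new lines
are assigned to the group with the smallest Mahalanobis distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_LEVELS = (0.5, 0.9)
#: canonical group order, also the tie-break order for assignment
GROUP_ORDER = ("control", "ATD", "CED")


# ---------------------------------------------------------------------------
# method agreement


@dataclass
class BlandAltmanResult:
    """Mean-difference agreement between two paired methods."""

    differences: np.ndarray  # a - b, per line
    bias: float
    sd: float
    loa_low: float  # bias - 2 SD
    loa_high: float  # bias + 2 SD
    all_within: bool


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman limits of agreement on paired per-line values.

    Differences are ``a - b``; limits are bias ± 2·SD (sample SD,
    n−1 denominator).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D and paired by line")
    if len(a) < 2:
        raise ValueError(f"need >= 2 pairs, got {len(a)}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 2 * sd, bias + 2 * sd
    within = bool(np.all((d >= lo - 1e-12) & (d <= hi + 1e-12)))
    return BlandAltmanResult(d, bias, sd, lo, hi, within)


def paired_two_sided_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided t-test; returns (t, p).

    Degenerate cases: all differences zero → (0, 1); zero-variance
    differences with nonzero mean → (±inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need >= 2 paired values")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# cohort model


@dataclass
class GroupModel:
    centroid: np.ndarray  # (2,)
    cov: np.ndarray  # (2, 2)
    n_lines: int

    def mahalanobis(self, point: np.ndarray) -> float:
        delta = np.asarray(point, dtype=float) - self.centroid
        return float(np.sqrt(delta @ np.linalg.solve(self.cov, delta)))


@dataclass
class CohortModel:
    """Per-group bivariate-normal model in the (length, IFT) plane."""

    groups: dict[str, GroupModel]
    levels: tuple[float, ...] = DEFAULT_LEVELS

    def chi2_radius(self, level: float) -> float:
        """Squared-Mahalanobis boundary value of the ellipse at a level
        (chi-square with 2 degrees of freedom)."""
        return float(stats.chi2.ppf(level, df=2))

    def inside(self, point: Sequence[float], group: str, level: float) -> bool:
        g = self.groups[group]
        return g.mahalanobis(np.asarray(point)) ** 2 <= self.chi2_radius(level)

    def ellipse_boundary(self, group: str, level: float,
                         n: int = 360) -> np.ndarray:
        """(n, 2) points on the group's confidence-ellipse boundary."""
        g = self.groups[group]
        vals, vecs = np.linalg.eigh(g.cov)
        vals = np.clip(vals, 0.0, None)
        r = np.sqrt(self.chi2_radius(level))
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        circ = np.column_stack([np.cos(theta), np.sin(theta)])
        return g.centroid + r * circ * np.sqrt(vals) @ vecs.T

    def to_json(self, path: str | Path) -> None:
        d = {
            "levels": list(self.levels),
            "groups": {
                name: {
                    "centroid": g.centroid.tolist(),
                    "cov": g.cov.tolist(),
                    "n_lines": g.n_lines,
                }
                for name, g in self.groups.items()
            },
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortModel":
        d = json.loads(Path(path).read_text())
        groups = {
            name: GroupModel(
                centroid=np.asarray(g["centroid"], dtype=float),
                cov=np.asarray(g["cov"], dtype=float),
                n_lines=int(g["n_lines"]),
            )
            for name, g in d["groups"].items()
        }
        return cls(groups=groups, levels=tuple(d.get("levels", DEFAULT_LEVELS)))


def _pooled_within_cov(groups: Mapping[str, np.ndarray]) -> np.ndarray:
    ssq = np.zeros((2, 2))
    n_tot = 0
    for pts in groups.values():
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 2:
            continue
        centered = pts - pts.mean(axis=0)
        ssq += centered.T @ centered
        n_tot += len(pts) - 1
    if n_tot == 0:
        return np.eye(2)
    return ssq / n_tot


def fit_cohort_model(
    groups: Mapping[str, np.ndarray],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    min_lines: int = 3,
    cov_floor: str | None = "pooled",
) -> CohortModel:
    """Fit per-group centroid + covariance over per-line medians.

    Each value of ``groups`` is an (n, 2) array of per-line
    (length µm, IFT µm²) medians.  Groups need at least ``min_lines``
    lines.  A group whose own covariance is unusable (fewer than 3
    lines, or numerically singular) falls back to the pooled
    within-group covariance when ``cov_floor="pooled"``; every
    covariance is regularized by +1e-9·I.
    """
    fitted: dict[str, GroupModel] = {}
    pooled = _pooled_within_cov(groups)
    for name, pts in groups.items():
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"group {name!r}: expected (n, 2) medians")
        if len(pts) < min_lines:
            raise ValueError(
                f"group {name!r} has {len(pts)} lines; >= {min_lines} required"
            )
        centroid = pts.mean(axis=0)
        if len(pts) >= 3:
            cov = np.cov(pts.T, ddof=1)
        else:
            cov = np.full((2, 2), np.nan)
        degenerate = (
            not np.all(np.isfinite(cov))
            or np.linalg.det(cov) < 1e-12 * max(np.trace(cov) ** 2, 1e-30)
        )
        if degenerate and cov_floor == "pooled":
            cov = pooled.copy()
        cov = cov + 1e-9 * np.eye(2)
        fitted[name] = GroupModel(centroid=centroid, cov=cov, n_lines=len(pts))
    return CohortModel(groups=fitted, levels=levels)


@dataclass
class ClusterAssignment:
    label: str
    distances: dict[str, float]  # Mahalanobis per group
    inside_09: dict[str, bool]
    tie: bool = False


def assign_cluster(point: Sequence[float], model: CohortModel) -> ClusterAssignment:
    """Assign a line's (length, IFT) median pair to the nearest group by
    Mahalanobis distance; exact ties break by canonical group order and
    are flagged.  ``inside_09`` reports 0.9-ellipse membership per group
    (all false = unclassifiable at 0.9)."""
    point = np.asarray(point, dtype=float)
    if point.shape != (2,) or not np.all(np.isfinite(point)):
        raise ValueError("point must be a finite (length, ift) pair")
    order = [g for g in GROUP_ORDER if g in model.groups]
    order += [g for g in model.groups if g not in order]
    dists = {g: model.groups[g].mahalanobis(point) for g in order}
    best = min(order, key=lambda g: dists[g])
    tie = sum(np.isclose(dists[g], dists[best], atol=1e-12) for g in order) > 1
    inside = {g: model.inside(point, g, 0.9) for g in order}
    return ClusterAssignment(label=best, distances=dists, inside_09=inside, tie=tie)


def ellipses_overlap(model: CohortModel, group_a: str, group_b: str,
                     level: float = 0.9, n: int = 720) -> bool:
    """Whether two groups' confidence ellipses at a level intersect
    (boundary sampling plus mutual-containment checks)."""
    c2 = model.chi2_radius(level)
    ga, gb = model.groups[group_a], model.groups[group_b]
    if ga.mahalanobis(gb.centroid) ** 2 <= c2 or gb.mahalanobis(ga.centroid) ** 2 <= c2:
        return True
    for bd, other in ((model.ellipse_boundary(group_a, level, n), gb),
                      (model.ellipse_boundary(group_b, level, n), ga)):
        d2 = np.array([other.mahalanobis(p) ** 2 for p in bd])
        if (d2 <= c2).any():
            return True
    return False


def leave_one_out_assignment(
    groups: Mapping[str, np.ndarray],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> tuple[int, int]:
    """Leave-one-out cluster recovery: for every line, refit the model
    without it and assign it; returns (n_correct, n_total).  Held-out
    groups may temporarily drop below 3 lines, in which case their
    covariance falls back to the pooled within-group covariance."""
    n_correct = 0
    n_total = 0
    for name, pts in groups.items():
        pts = np.asarray(pts, dtype=float)
        for i in range(len(pts)):
            loo = {k: (np.delete(v, i, axis=0) if k == name else np.asarray(v))
                   for k, v in groups.items()}
            model = fit_cohort_model(loo, levels=levels, min_lines=2)
            if assign_cluster(pts[i], model).label == name:
                n_correct += 1
            n_total += 1
    return n_correct, n_total


def plot_cohort(model: CohortModel, points: Mapping[str, np.ndarray],
                path: str | Path, extra: Mapping[str, Sequence[float]] | None = None
                ) -> None:
    """Write the cluster plot: per-line dots, and 0.5 / 0.9 confidence
    ellipses per fitted group.  ``extra`` marks unassigned lines."""
    from matplotlib.figure import Figure

    colors = {"control": "tab:green", "ATD": "tab:blue", "CED": "tab:red"}
    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    for name, g in model.groups.items():
        col = colors.get(name, "tab:gray")
        pts = np.asarray(points.get(name, np.empty((0, 2))))
        if len(pts):
            ax.plot(pts[:, 0], pts[:, 1], "o", color=col, label=name, ms=6)
        for level, ls in zip(model.levels, ("-", "--")):
            bd = model.ellipse_boundary(name, level)
            bd = np.vstack([bd, bd[:1]])
            ax.plot(bd[:, 0], bd[:, 1], ls, color=col, lw=1.2,
                    label=f"{name} CI {level}" if len(model.levels) < 3 else None)
    if extra:
        for label, pt in extra.items():
            ax.plot(pt[0], pt[1], "k*", ms=10)
            ax.annotate(label, pt, textcoords="offset points", xytext=(4, 4),
                        fontsize=8)
    ax.set_xlabel("median cilium length (µm)")
    ax.set_ylabel("median IFT88 area (µm²)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
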
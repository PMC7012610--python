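"""Statistics over per-cell coverage tables: positive calls, channel
co-expression, medial/lateral density profiles, starter-cell composition,
and rabies-input proportions with per-animal mean ± SEM.

The coverage cutoff that turns a coverage percentage into a "+" call is
an explicit analysis parameter (default 5%) and is stamped into every
report: the field has no published standard for this criterion, so it
must never be implicit. Error bars are computed across animals
(biological replicates), not across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Default coverage (%) above which a cell is called positive for a channel.
DEFAULT_CUTOFF = 5.0

_META_COLS = {"image_id", "animal_id", "centroid_row", "centroid_col", "area"}


@dataclass
class AxisAnnotation:
    """Medial/lateral axis annotation for one image.

    The axis runs from the medial anchor (position 0) to the lateral
    anchor (position 1); an optional region polygon restricts which cells
    are scored, and an optional anterior/posterior label (mm from bregma)
    supports A/P range filtering.
    """

    medial_anchor: tuple[float, float]  # (row, col)
    lateral_anchor: tuple[float, float]
    polygon: list[tuple[float, float]] | None = None
    ap_mm: float | None = None

    def __post_init__(self) -> None:
        if np.allclose(self.medial_anchor, self.lateral_anchor):
            raise ValueError("medial and lateral anchors coincide")


@dataclass
class ProportionReport:
    """Per-marker proportions of a cell population, across animals."""

    per_animal: pd.DataFrame  # animals x markers, proportions in [0, 1]
    mean: pd.Series
    sem: pd.Series
    n_cells: int
    n_animals: int
    cutoff: dict = field(default_factory=dict)
    sem_defined: bool = True


def _channel_cols(coverage: pd.DataFrame) -> list[str]:
    return [c for c in coverage.columns if c not in _META_COLS]


def classify_positive(
    coverage: pd.DataFrame, cutoff: float | dict = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Threshold coverage (%) into boolean positive calls per channel.

    ``cutoff`` is a single percentage or a per-channel dict; a cell is
    positive when coverage >= cutoff. The cutoffs used are recorded in
    ``result.attrs['cutoff']``.
    """
    channels = _channel_cols(coverage)
    if isinstance(cutoff, dict):
        cut = {c: float(cutoff.get(c, DEFAULT_CUTOFF)) for c in channels}
    else:
        cut = {c: float(cutoff) for c in channels}
    if any(v < 0 for v in cut.values()):
        raise ValueError("cutoff must be >= 0")
    calls = coverage.copy()
    for c in channels:
        calls[c] = coverage[c] >= cut[c]
    calls.attrs["cutoff"] = cut
    return calls


def overlap_table(calls: pd.DataFrame, ch_a: str, ch_b: str) -> pd.DataFrame:
    """2×2 contingency counts of positive calls for two channels."""
    for ch in (ch_a, ch_b):
        if ch not in calls.columns:
            raise KeyError(f"channel {ch!r} not in calls table")
    a = calls[ch_a].to_numpy(dtype=bool)
    b = calls[ch_b].to_numpy(dtype=bool)
    return pd.DataFrame(
        [[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]],
        index=pd.Index([f"{ch_a}+", f"{ch_a}-"]),
        columns=pd.Index([f"{ch_b}+", f"{ch_b}-"]),
    )


def ml_position(
    centroids: np.ndarray, annotation: AxisAnnotation
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized medial/lateral position of each centroid.

    Scalar projection onto the medial→lateral anchor axis, clipped to
    [0, 1]. When the annotation carries a polygon, centroids outside it
    are excluded (with a warning); the boolean ``included`` mask is
    returned alongside the positions of the included cells.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    m = np.asarray(annotation.medial_anchor, dtype=float)
    l = np.asarray(annotation.lateral_anchor, dtype=float)
    axis = l - m
    included = np.ones(len(pts), dtype=bool)
    if annotation.polygon is not None:
        from matplotlib.path import Path as MplPath

        poly = MplPath(np.asarray(annotation.polygon, dtype=float))
        included = poly.contains_points(pts, radius=1e-9) | poly.contains_points(
            pts, radius=-1e-9
        )
        if not included.all():
            warnings.warn(
                f"excluding {int((~included).sum())} centroid(s) outside the polygon"
            )
    proj = (pts[included] - m) @ axis / (axis @ axis)
    return np.clip(proj, 0.0, 1.0), included


def density_histogram(
    positions: np.ndarray | pd.Series,
    n_bins: int = 10,
    animal_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of cells per medial/lateral bin.

    Bins are half-open [l, r) on [0, 1] with the last bin closed. With
    ``animal_ids``, fractions are computed per animal and averaged, with
    SEM across animals; otherwise a single pooled profile is returned.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("no cells to histogram")
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def frac(pos):
        counts, _ = np.histogram(pos, bins=edges)
        return counts / pos.size

    centers = (edges[:-1] + edges[1:]) / 2
    if animal_ids is None:
        return pd.DataFrame({"bin_center": centers, "fraction": frac(positions)})
    animal_ids = np.asarray(animal_ids)
    per_animal = np.vstack(
        [frac(positions[animal_ids == a]) for a in pd.unique(animal_ids)]
    )
    n_animals = per_animal.shape[0]
    sem = (
        per_animal.std(axis=0, ddof=1) / np.sqrt(n_animals)
        if n_animals > 1
        else np.zeros(n_bins)
    )
    return pd.DataFrame(
        {
            "bin_center": centers,
            "fraction": per_animal.mean(axis=0),
            "sem": sem,
        }
    )


def ap_filter(
    cells: pd.DataFrame, range_mm: tuple[float, float], ap_column: str = "ap_mm"
) -> pd.DataFrame:
    """Keep cells whose anterior/posterior position lies in the inclusive
    range (e.g. −1.855 to −1.655 mm from bregma, excluding the habenula's
    A/P poles before medial/lateral histograms)."""
    if ap_column not in cells.columns:
        raise KeyError(f"column {ap_column!r} missing")
    ap = cells[ap_column]
    if ap.isna().any():
        raise ValueError(
            f"cells without A/P label: {list(cells.index[ap.isna()])}"
        )
    lo, hi = min(range_mm), max(range_mm)
    return cells[(ap >= lo) & (ap <= hi)]


def _per_animal_proportions(calls, markers, animal_col="animal_id"):
    rows = {}
    for animal, grp in calls.groupby(animal_col, sort=True):
        rows[animal] = {m: float(grp[m].mean()) for m in markers}
    return pd.DataFrame(rows).T


def tracing_proportions(
    calls: pd.DataFrame,
    markers: list[str],
    rbv_channel: str = "RbV-N",
    animal_col: str = "animal_id",
) -> ProportionReport:
    """Marker composition of retrogradely labeled (RbV-N+) cells.

    Per animal, the fraction of RbV-N+ cells positive for each marker;
    the report carries the across-animal mean and SEM (sd/√n_animals).
    Animals with no RbV-N+ cell are excluded with a warning; with a
    single animal the SEM is reported as 0 and flagged undefined.
    """
    rbv = calls[calls[rbv_channel].astype(bool)]
    kept = []
    for animal, grp in rbv.groupby(animal_col):
        kept.append(animal)
    dropped = set(calls[animal_col].unique()) - set(kept)
    if dropped:
        warnings.warn(f"animals without RbV-N+ cells excluded: {sorted(dropped)}")
    per_animal = _per_animal_proportions(rbv, markers, animal_col)
    n_animals = len(per_animal)
    mean = per_animal.mean(axis=0)
    sem_defined = n_animals > 1
    sem = (
        per_animal.std(axis=0, ddof=1) / np.sqrt(n_animals)
        if sem_defined
        else pd.Series(0.0, index=mean.index)
    )
    return ProportionReport(
        per_animal=per_animal,
        mean=mean,
        sem=sem,
        n_cells=len(rbv),
        n_animals=n_animals,
        cutoff=dict(calls.attrs.get("cutoff", {})),
        sem_defined=sem_defined,
    )


def starter_composition(
    calls: pd.DataFrame,
    starter_channels: list[str],
    markers: list[str],
    animal_col: str = "animal_id",
) -> ProportionReport:
    """Marker composition of starter cells (positive for every
    starter-defining channel, e.g. GFP and Cre)."""
    mask = np.ones(len(calls), dtype=bool)
    for ch in starter_channels:
        if ch not in calls.columns:
            raise KeyError(f"starter channel {ch!r} missing")
        mask &= calls[ch].to_numpy(dtype=bool)
    starters = calls[mask]
    if len(starters) == 0:
        raise ValueError("no starter cells")
    per_animal = _per_animal_proportions(starters, markers, animal_col)
    n_animals = len(per_animal)
    mean = per_animal.mean(axis=0)
    sem_defined = n_animals > 1
    sem = (
        per_animal.std(axis=0, ddof=1) / np.sqrt(n_animals)
        if sem_defined
        else pd.Series(0.0, index=mean.index)
    )
    return ProportionReport(
        per_animal=per_animal,
        mean=mean,
        sem=sem,
        n_cells=len(starters),
        n_animals=n_animals,
        cutoff=dict(calls.attrs.get("cutoff", {})),
        sem_defined=sem_defined,
    )


def compare_proportions(
    report_a: ProportionReport, report_b: ProportionReport
) -> pd.DataFrame:
    """Per-marker two-sided Welch t-test on per-animal proportions, with
    Holm correction across markers. The test used is recorded in the
    output so downstream reports can cite it."""
    if report_a.n_animals < 2 or report_b.n_animals < 2:
        raise ValueError("compare_proportions needs >= 2 animals per condition")
    markers = [m for m in report_a.per_animal.columns if m in report_b.per_animal]
    rows = []
    for m in markers:
        t, p = stats.ttest_ind(
            report_a.per_animal[m], report_b.per_animal[m], equal_var=False
        )
        rows.append({"marker": m, "t": float(t), "p_val": float(p)})
    table = pd.DataFrame(rows)
    # Holm step-down correction
    order = np.argsort(table["p_val"].to_numpy())
    n = len(table)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * table["p_val"].iloc[idx])
        adj[idx] = min(1.0, running)
    table["p_val_adj"] = adj
    table["method"] = "welch_t_holm"
    return table
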
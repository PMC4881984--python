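"""Count-based phagocytosis efficiency metrics.

Quantifies how well microglia keep up with apoptosis from stereological
cell censuses: per sampled region one records the total number of
apoptotic cells (pyknotic/karyorrhectic nuclei), how many of those sit
inside a closed microglial pouch, the number of microglia, and a
histogram of microglia by number of phagocytic pouches.  From these the
standard efficiency metrics follow:

* **Ph index** — fraction of apoptotic cells already engulfed,
  ``apo_phagocytosed / apo_total``.
* **Ph capacity** — mean number of phagocytic pouches per microglia
  (parts per unit, ppu), the histogram-weighted mean ``sum n * mg_n / mg``.
* **Net phagocytosis** — microglia count x Ph capacity, i.e. the number
  of cells currently being engulfed by the whole population.
* **Ph/A coupling** — net phagocytosis over total apoptosis; reported as
  fold change against a baseline (control) group so that coupling = 1
  means phagocytosis scales with apoptosis.

All internal values are fractions; percentage formatting belongs to the
reporting layer.  Undefined metrics (zero denominators) raise
:class:`~phagoquant.errors.UndefinedMetricError` rather than returning 0,
because "no apoptotic cells" means the index is unestimable, not zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "CellCensus",
    "PhagocytosisSummary",
    "DEFAULT_DISTANCE_BIN_EDGES",
    "ph_index",
    "weighted_capacity",
    "net_phagocytosis",
    "php_capacity",
    "ph_a_coupling",
    "cell_density",
    "distance_histogram",
    "linear_r2",
    "summarize_census",
    "summarize_censuses",
    "baseline_mean_coupling",
]

#: Distance bins (um) for apoptotic-cell -> nearest-microglial-process
#: histograms: touching (<0.5), near (0.5-3), intermediate (3-10), far (>10).
DEFAULT_DISTANCE_BIN_EDGES: tuple[float, ...] = (0.0, 0.5, 3.0, 10.0, math.inf)


@dataclass(frozen=True)
class CellCensus:
    """One sampled region's cell counts.

    ``pouch_histogram`` maps pouch count ``n >= 1`` to the number of
    microglia carrying exactly ``n`` phagocytic pouches; microglia with
    zero pouches are implicit (``microglia_total`` minus the histogram
    sum), so input tables may list only the phagocytic cells.
    ``phagoptosis_histogram`` is the analogous histogram for pouches
    containing nonapoptotic (phagoptosed) cells.
    """

    sample_id: str
    group: str
    apo_total: int
    apo_phagocytosed: int
    microglia_total: int
    pouch_histogram: Mapping[int, int] = field(default_factory=dict)
    phagoptosis_histogram: Mapping[int, int] | None = None
    region_volume_mm3: float = 1.0
    distances_um: Sequence[float] | None = None

    def __post_init__(self) -> None:
        for name in ("apo_total", "apo_phagocytosed", "microglia_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} < 0 in sample {self.sample_id!r}")
        if self.apo_phagocytosed > self.apo_total:
            raise ValidationError(
                f"apo_phagocytosed > apo_total in sample {self.sample_id!r}"
            )
        if self.region_volume_mm3 <= 0:
            raise ValidationError(
                f"region_volume_mm3 must be > 0 in sample {self.sample_id!r}"
            )
        _check_histogram(self.pouch_histogram, self.microglia_total, self.sample_id)
        if self.phagoptosis_histogram is not None:
            _check_histogram(
                self.phagoptosis_histogram, self.microglia_total, self.sample_id
            )
        if self.distances_um is not None and any(d < 0 for d in self.distances_um):
            raise ValidationError(f"negative distance in sample {self.sample_id!r}")


def _check_histogram(hist: Mapping[int, int], total: int, sample_id: str) -> None:
    for n, count in hist.items():
        if n < 1:
            raise ValidationError(
                f"pouch histogram key {n} < 1 in sample {sample_id!r} "
                "(cells with 0 pouches are implicit)"
            )
        if count < 0:
            raise ValidationError(f"negative histogram count in sample {sample_id!r}")
    if sum(hist.values()) > total:
        raise ValidationError(
            f"pouch histogram counts exceed microglia_total in sample {sample_id!r}"
        )


@dataclass(frozen=True)
class PhagocytosisSummary:
    """Per-sample metric bundle; ``None`` marks an undefined metric."""

    sample_id: str
    group: str
    ph_index: float | None
    ph_capacity: float
    php_capacity: float | None
    net_phagocytosis: float
    ph_a_coupling: float | None
    ph_a_fold_change: float | None
    apoptotic_density_mm3: float
    microglia_density_mm3: float
    notes: tuple[str, ...] = ()


def ph_index(census: CellCensus) -> float:
    """Fraction of apoptotic cells engulfed by microglia, in [0, 1]."""
    if census.apo_total == 0:
        raise UndefinedMetricError(
            "ph_index", "zero_apoptotic_cells", census.sample_id
        )
    return census.apo_phagocytosed / census.apo_total


def weighted_capacity(histogram: Mapping[int, int], total_cells: int) -> float:
    """Mean number of pouches per cell (ppu) from a pouch-count histogram.

    Equals ``sum(n * count_n) / total_cells``; cells absent from the
    histogram are counted as carrying zero pouches.
    """
    if total_cells == 0:
        raise UndefinedMetricError("weighted_capacity", "zero_total_cells")
    _check_histogram(histogram, total_cells, "<anonymous>")
    return sum(n * c for n, c in histogram.items()) / total_cells


def net_phagocytosis(census: CellCensus) -> float:
    """Microglia count x phagocytic capacity: cells being engulfed right now."""
    if census.microglia_total == 0:
        return 0.0
    return census.microglia_total * weighted_capacity(
        census.pouch_histogram, census.microglia_total
    )


def php_capacity(census: CellCensus) -> float | None:
    """Weighted phagoptosis capacity (pouches holding nonapoptotic cells)."""
    if census.phagoptosis_histogram is None:
        return None
    if census.microglia_total == 0:
        raise UndefinedMetricError("php_capacity", "zero_microglia", census.sample_id)
    return weighted_capacity(census.phagoptosis_histogram, census.microglia_total)


def ph_a_coupling(
    census: CellCensus, baseline_raw: float | None = None
) -> tuple[float, float | None]:
    """Raw Ph/A coupling and, given a baseline, its fold change.

    Raw coupling is net phagocytosis over total apoptosis,
    ``(capacity * microglia) / apo_total``.  ``baseline_raw`` is the mean
    raw coupling of the designated baseline group (see
    :func:`baseline_mean_coupling`); fold change divides by it so a
    control sample plots at ~1.
    """
    if census.apo_total == 0:
        raise UndefinedMetricError(
            "ph_a_coupling", "zero_apoptotic_cells", census.sample_id
        )
    raw = net_phagocytosis(census) / census.apo_total
    if baseline_raw is None:
        return raw, None
    if baseline_raw <= 0:
        raise UndefinedMetricError(
            "ph_a_fold_change", "zero_baseline_coupling", census.sample_id
        )
    return raw, raw / baseline_raw


def cell_density(count: int, volume_mm3: float) -> float:
    """Cells per mm^3."""
    if volume_mm3 <= 0:
        raise ValidationError("volume must be > 0")
    return count / volume_mm3


def distance_histogram(
    distances: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_DISTANCE_BIN_EDGES,
) -> np.ndarray:
    """Proportion of apoptotic cells per distance-to-process bin.

    Bins are half-open ``[lo, hi)`` and the last bin is open-ended; the
    returned proportions sum to 1.
    """
    if len(distances) == 0:
        raise UndefinedMetricError("distance_histogram", "no_distances")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be strictly increasing")
    counts, _ = np.histogram(np.asarray(distances, dtype=float), bins=edges)
    return counts / counts.sum()


def linear_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Ordinary-least-squares coefficient of determination of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("linear_r2", "constant_x")
    result = stats.linregress(x, y)
    return float(result.rvalue**2)


def baseline_mean_coupling(
    censuses: Sequence[CellCensus], baseline_group: str
) -> float:
    """Mean raw Ph/A coupling over the named baseline group."""
    raws = [
        ph_a_coupling(c)[0]
        for c in censuses
        if c.group == baseline_group and c.apo_total > 0
    ]
    if not raws:
        raise UndefinedMetricError(
            "baseline_mean_coupling", f"no_usable_samples_in_group:{baseline_group}"
        )
    return float(np.mean(raws))


def summarize_census(
    census: CellCensus, baseline_raw: float | None = None
) -> PhagocytosisSummary:
    """All metrics for one census; undefined metrics become None + note."""
    notes: list[str] = []
    try:
        phi: float | None = ph_index(census)
    except UndefinedMetricError as exc:
        phi = None
        notes.append(f"ph_index:{exc.reason}")
    capacity = (
        weighted_capacity(census.pouch_histogram, census.microglia_total)
        if census.microglia_total > 0
        else 0.0
    )
    net = net_phagocytosis(census)
    try:
        raw, fold = ph_a_coupling(census, baseline_raw)
    except UndefinedMetricError as exc:
        raw, fold = None, None
        notes.append(f"ph_a_coupling:{exc.reason}")
    return PhagocytosisSummary(
        sample_id=census.sample_id,
        group=census.group,
        ph_index=phi,
        ph_capacity=capacity,
        php_capacity=php_capacity(census) if census.phagoptosis_histogram else None,
        net_phagocytosis=net,
        ph_a_coupling=raw,
        ph_a_fold_change=fold,
        apoptotic_density_mm3=cell_density(census.apo_total, census.region_volume_mm3),
        microglia_density_mm3=cell_density(
            census.microglia_total, census.region_volume_mm3
        ),
        notes=tuple(notes),
    )


def summarize_censuses(
    censuses: Sequence[CellCensus], baseline_group: str | None = None
) -> pd.DataFrame:
    """Per-sample summary table; fold changes vs the baseline group mean."""
    baseline_raw = (
        baseline_mean_coupling(censuses, baseline_group) if baseline_group else None
    )
    def _num(value: float | None) -> float:
        return float("nan") if value is None else value

    rows = []
    for census in censuses:
        s = summarize_census(census, baseline_raw)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "ph_index": _num(s.ph_index),
                "ph_capacity_ppu": s.ph_capacity,
                "php_capacity_ppu": _num(s.php_capacity),
                "net_phagocytosis": s.net_phagocytosis,
                "ph_a_coupling": _num(s.ph_a_coupling),
                "ph_a_fold_change": _num(s.ph_a_fold_change),
                "apoptotic_density_mm3": s.apoptotic_density_mm3,
                "microglia_density_mm3": s.microglia_density_mm3,
                "notes": ";".join(s.notes),
            }
        )
    return pd.DataFrame(rows)
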
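"""Seed-deterministic synthetic data with known ground truth.

Every analysis stage has a generator that emulates the statistical
structure of its real input:

* cell censuses with Poisson cell counts and binomial engulfment, in a
  *coupled* regime (phagocytosis scales with an apoptotic challenge, so
  the Ph/A fold change stays near 1) or an *uncoupled* regime (engulfment
  probability collapses while apoptosis rises);
* pulse-chase cohorts in which cells enter apoptosis as a Poisson process
  and are cleared after an exponential waiting time with mean tau;
* 4-D two-photon phantoms: a tube with Gaussian cross-section rendered
  along a known centerline per frame, at the real acquisition geometry
  (0.1 x 0.1 x 1 um voxels, 1.5 min frames), with the analytic centerline
  arc length emitted as ground truth;
* Ct tables generated from known fold changes and amplification
  efficiencies.

All generators take a seed and an optional stream id, so the same seed
reproduces byte-identical outputs and generators do not perturb each
other.  Ground truth is returned as separate objects (and written to
sidecar files by the CLI), never embedded in the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import CellCensus
from .errors import ValidationError
from .motility import (
    DEFAULT_FRAME_INTERVAL_MIN,
    DEFAULT_VOXEL_SIZE_UM,
    ZStackSeries,
)

__all__ = [
    "generate_census",
    "generate_clearance_cohort",
    "generate_process_stack",
    "generate_ct_table",
    "StackTruth",
]

# fixed sub-stream ids so adding a generator never perturbs the others
_STREAMS = {"census": 1, "cohort": 2, "stack": 3, "ct": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# censuses


def generate_census(
    seed: int,
    scenario: str = "coupled",
    n_samples: int = 30,
    mean_apoptotic: float = 40.0,
    engulfment_p: float = 0.9,
    mean_microglia: float = 300.0,
    region_volume_mm3: float = 0.05,
    challenge_factor: float = 3.0,
    uncoupled_engulfment_p: float = 0.3,
    with_distances: bool = False,
) -> list[CellCensus]:
    """Censuses for a control and a challenge group.

    Control samples draw ``apo_total ~ Poisson(mean_apoptotic)``, engulf
    each apoptotic cell independently with probability ``engulfment_p``
    (physiological engulfment is ~0.9), and assign engulfed cells to
    microglia at random, which builds the pouch histogram.  The challenge
    group multiplies apoptosis by ``challenge_factor``; in the *coupled*
    scenario the engulfment probability is unchanged, so net phagocytosis
    scales with apoptosis and the expected Ph/A fold change is 1 (the
    extra load is absorbed by more microglia becoming phagocytic and by
    higher per-cell capacity).  In the *uncoupled* scenario the challenge
    group engulfs with ``uncoupled_engulfment_p`` instead, so Ph index
    and Ph/A coupling drop.
    """
    if scenario not in ("coupled", "uncoupled"):
        raise ValidationError(f"unknown scenario {scenario!r}")
    for p in (engulfment_p, uncoupled_engulfment_p):
        if not (0 <= p <= 1):
            raise ValidationError("engulfment probabilities must be in [0, 1]")
    rng = _rng(seed, "census")
    censuses: list[CellCensus] = []
    groups = (
        ("control", mean_apoptotic, engulfment_p),
        (
            "challenge",
            mean_apoptotic * challenge_factor,
            engulfment_p if scenario == "coupled" else uncoupled_engulfment_p,
        ),
    )
    for group, mu_apo, p_eng in groups:
        for i in range(n_samples):
            apo = int(rng.poisson(mu_apo))
            engulfed = int(rng.binomial(apo, p_eng)) if apo else 0
            mg = max(int(rng.poisson(mean_microglia)), 1)
            hist = _occupancy_histogram(rng, engulfed, mg)
            distances = (
                tuple(rng.exponential(2.0, size=apo)) if with_distances and apo else None
            )
            censuses.append(
                CellCensus(
                    sample_id=f"{group}_{i:03d}",
                    group=group,
                    apo_total=apo,
                    apo_phagocytosed=engulfed,
                    microglia_total=mg,
                    pouch_histogram=hist,
                    region_volume_mm3=region_volume_mm3,
                    distances_um=distances,
                )
            )
    return censuses


def _occupancy_histogram(
    rng: np.random.Generator, n_cells: int, n_microglia: int
) -> dict[int, int]:
    """Assign engulfed cells to microglia uniformly; histogram of pouch counts."""
    if n_cells == 0:
        return {}
    per_mg = rng.multinomial(n_cells, np.full(n_microglia, 1.0 / n_microglia))
    values, counts = np.unique(per_mg[per_mg > 0], return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


# ---------------------------------------------------------------------------
# clearance cohorts


def generate_clearance_cohort(
    seed: int,
    tau_h: float,
    production_rate_per_h: float = 100.0,
    t_max_h: float | None = None,
    n_times: int = 50,
) -> pd.DataFrame:
    """Simulated pulse-chase cohort tallies.

    Cells enter apoptosis as a homogeneous Poisson process at
    ``production_rate_per_h`` and each is cleared after an independent
    exponential waiting time with mean ``tau_h``.  Returns a tidy series
    of (time_h, present, cleared_cum) at ``n_times`` sample times; the
    default horizon ``t_max_h = 20 * tau_h`` reaches steady state, where
    the expected present count is rate x tau.
    """
    if tau_h <= 0 or production_rate_per_h <= 0:
        raise ValidationError("tau and production rate must be > 0")
    rng = _rng(seed, "cohort")
    t_max = 20.0 * tau_h if t_max_h is None else float(t_max_h)
    n_events = rng.poisson(production_rate_per_h * t_max)
    entry = np.sort(rng.uniform(0.0, t_max, size=n_events))
    exit_ = entry + rng.exponential(tau_h, size=n_events)
    times = np.linspace(t_max / n_times, t_max, n_times)
    present = np.empty(n_times)
    cleared = np.empty(n_times)
    for i, t in enumerate(times):
        entered = entry <= t
        gone = exit_ <= t
        present[i] = np.count_nonzero(entered & ~gone)
        cleared[i] = np.count_nonzero(gone)
    return pd.DataFrame({"time_h": times, "present": present, "cleared_cum": cleared})


# ---------------------------------------------------------------------------
# process phantoms


@dataclass(frozen=True)
class StackTruth:
    """Ground truth accompanying a phantom stack."""

    lengths_um: tuple[float, ...]  # analytic centerline arc length per frame
    background: float
    amplitude: float
    centerlines_px: tuple[np.ndarray, ...]  # per frame: columns (y, xc, zc)


def generate_process_stack(
    seed: int,
    lengths_um: Sequence[float] = (20.0,) * 10,
    amplitude_um: float = 1.0,
    wavelength_um: float = 15.0,
    z_amplitude_um: float = 0.0,
    sigma_x_um: float = 0.3,
    sigma_z_um: float = 0.8,
    peak_intensity: float = 100.0,
    snr: float | None = None,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    n_z: int = 11,
) -> tuple[ZStackSeries, StackTruth]:
    """Render a tubular process phantom with a known centerline per frame.

    Per frame f the tube spans ``lengths_um[f]`` of y-extent starting
    from the bottom of the field; its centerline wiggles sinusoidally in
    x (and optionally z) with the given amplitude and wavelength.  The
    cross-section in each xz plane is a separable Gaussian, so every
    y-line through the tube carries a clean single-peaked profile, and
    the ends are sharp in y.  ``snr`` adds white Gaussian noise with
    sigma = peak / snr.  Ground truth is the analytic polyline arc length
    of the rendered centerline (which exceeds the commanded y-extent when
    the centerline is curved).
    """
    dx, dy, dz = voxel_size_um
    max_extent = max(lengths_um)
    ny = int(round(max_extent / dy)) + 20
    x0_um = 2.0 + amplitude_um  # tube kept clear of the field border
    nx = int(round(2 * x0_um / dx)) + 1
    z0 = (n_z - 1) / 2.0
    if x0_um + amplitude_um + 4 * sigma_x_um > nx * dx or n_z < 3:
        raise ValidationError("tube does not fit inside the stack")
    rng = _rng(seed, "stack")
    n_frames = len(lengths_um)
    data = np.zeros((n_frames, n_z, ny, nx), dtype=float)
    xs_px = np.arange(nx)
    zs_px = np.arange(n_z)
    truths: list[float] = []
    centerlines: list[np.ndarray] = []
    for f, extent in enumerate(lengths_um):
        n_lines = int(round(extent / dy))
        if n_lines < 2 or n_lines > ny:
            raise ValidationError(f"frame {f}: commanded length {extent} um invalid")
        y_idx = np.arange(10, 10 + n_lines)
        y_um = (y_idx - y_idx[0]) * dy
        xc_um = x0_um + amplitude_um * np.sin(2 * np.pi * y_um / wavelength_um)
        zc_um = z0 * dz + z_amplitude_um * np.sin(2 * np.pi * y_um / wavelength_um)
        xc_px = xc_um / dx
        zc_px = zc_um / dz
        # separable Gaussian cross-section in the xz plane of each line
        gx = np.exp(
            -((xs_px[None, :] - xc_px[:, None]) * dx) ** 2 / (2 * sigma_x_um**2)
        )  # (y, x)
        gz = np.exp(
            -((zs_px[None, :] - zc_px[:, None]) * dz) ** 2 / (2 * sigma_z_um**2)
        )  # (y, z)
        data[f, :, y_idx, :] = peak_intensity * gz[:, :, None] * gx[:, None, :]
        seg = np.sqrt(
            np.diff(y_um) ** 2 + np.diff(xc_um) ** 2 + np.diff(zc_um) ** 2
        )
        truths.append(float(seg.sum()))
        centerlines.append(np.column_stack([y_idx, xc_px, zc_px]))
    if snr is not None:
        if snr <= 0:
            raise ValidationError("snr must be > 0")
        data = data + rng.normal(0.0, peak_intensity / snr, size=data.shape)
    stack = ZStackSeries(
        data=data,
        voxel_size_um=voxel_size_um,
        frame_interval_min=frame_interval_min,
    )
    truth = StackTruth(
        lengths_um=tuple(truths),
        background=0.0,
        amplitude=peak_intensity,
        centerlines_px=tuple(centerlines),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# qPCR


def generate_ct_table(
    seed: int,
    fold_changes: Mapping[str, float],
    efficiencies: Mapping[str, float],
    reference_gene: str = "ref",
    n_samples_per_group: int = 4,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    base_ct: float = 22.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table from known fold changes and amplification efficiencies.

    Control-group abundance is 1 for every gene; treated-group abundance
    of each target gene is its true fold change (the reference gene stays
    at 1).  Cts follow ``Ct = base_ct - log_(1+eff)(abundance) + noise``.
    Returns (long Ct table, truth table of fold changes).
    """
    for gene, eff in efficiencies.items():
        if not (0 < eff <= 1.2):
            raise ValidationError(f"efficiency for {gene!r} must be in (0, 1.2]")
    if reference_gene not in efficiencies:
        raise ValidationError("efficiencies must include the reference gene")
    rng = _rng(seed, "ct")
    genes = {reference_gene: 1.0, **dict(fold_changes)}
    rows = []
    for group, treated in (("control", False), ("treated", True)):
        for s in range(n_samples_per_group):
            sample_id = f"{group}_{s:02d}"
            for gene, fold in genes.items():
                abundance = fold if treated else 1.0
                ct = base_ct - np.log(abundance) / np.log(1 + efficiencies[gene])
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "ct": ct + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                        }
                    )
    truth = pd.DataFrame(
        [{"gene": g, "true_fold_change": f} for g, f in fold_changes.items()]
    )
    return pd.DataFrame(rows), truth
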
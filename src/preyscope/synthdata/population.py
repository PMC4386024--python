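"""Planted cell populations with known ground-truth tuning.

Archetypes emulate the functional cell classes seen in the anterior tectal
field during the virtual hunting assay:

* luminance cells -- ON (enriched at the rostral torus longitudinalis),
  dimming detectors, and luminance-inhibited cells (habenula/TL/tectum);
* mixed-selectivity spot clusters -- direction-selective cells preferring
  large bright spots, planted as left/right mirror pairs whose response
  latency follows the retinotopic sweep of the stimulus;
* the six NLMS classes (nDS-nSp ... L2R-Sp), tuned to large dark spots with
  optional speed/direction selectivity and a frontal receptive field;
* premotor assembly cells -- spatially compact unilateral SPV groups that
  burst a few frames before their designated convergent saccade (plus a
  weak visual response, as assembly members are typically also visually
  responsive);
* non-responsive cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..nlms import REGRESSOR_KEYS, build_regressors
from ..rois import ROIRecord, RegionMap
from ..stimulus import N_SPOT_STIMULI, feature_code

LUMINANCE_ARCHETYPES = ("lum_on", "lum_dimming", "lum_inhibited")
SPOT_CLUSTER_ARCHETYPES = (
    "bright_RL_left",   # prefers large bright right-to-left spots, left OTc
    "bright_RL_right",
    "bright_LR_left",
    "bright_LR_right",
)
NLMS_ARCHETYPES = tuple(f"nlms_{k}" for k in REGRESSOR_KEYS)

DEFAULT_MIXTURE = {
    "nonresponsive": 0.40,
    "lum_on": 0.10,
    "lum_dimming": 0.04,
    "lum_inhibited": 0.04,
    "bright_RL_left": 0.03,
    "bright_RL_right": 0.03,
    "bright_LR_left": 0.03,
    "bright_LR_right": 0.03,
    "nlms_nDS-nSp": 0.04,
    "nlms_nDS-Sp": 0.02,
    "nlms_R2L-nSp": 0.03,
    "nlms_R2L-Sp": 0.02,
    "nlms_L2R-nSp": 0.03,
    "nlms_L2R-Sp": 0.02,
    "assembly": 0.14,
}


@dataclass
class GeometryParams:
    """Placement parameters of the synthetic population."""

    n_rois: int = 400
    n_fish: int = 8
    region_map: RegionMap = field(default_factory=RegionMap.default)
    #: fraction of ON cells placed in the torus longitudinalis
    on_tl_fraction: float = 0.41
    #: spatial SD of assembly member scatter, um
    assembly_scale_um: float = 15.0
    assembly_size_range: tuple[int, int] = (8, 15)
    #: frames of premotor lead of assembly bursts (inclusive range)
    assembly_lead_range: tuple[int, int] = (1, 4)


@dataclass
class CellTruth:
    """Ground-truth tuning of one planted ROI."""

    roi_id: int
    archetype: str
    amplitude: float = 1.0
    w16: Optional[np.ndarray] = None        # spot-stimulus weights
    rf_azimuth: Optional[float] = None      # deg; None = sustained response
    lum_gain: float = 0.0                   # signed gain to luminance steps
    dimming_gain: float = 0.0
    assembly_id: Optional[int] = None
    latency_s: float = 0.0


@dataclass
class AssemblyTruth:
    assembly_id: int
    hemisphere: str
    member_roi_ids: list[int]
    lead_frames: int
    center: tuple[float, float]
    event_index: Optional[int] = None       # filled when traces are rendered


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for recovery tests."""

    seed: int
    cells: dict[int, CellTruth] = field(default_factory=dict)
    assemblies: list[AssemblyTruth] = field(default_factory=list)
    true_saccades: list = field(default_factory=list)

    def archetype_of(self, roi_id: int) -> str:
        return self.cells[roi_id].archetype


def _spot_weights_bright_ds(direction_bit: int) -> np.ndarray:
    """Large, bright spots moving in one direction."""
    w = np.zeros(N_SPOT_STIMULI)
    for sid in range(N_SPOT_STIMULI):
        d, s, z, p = feature_code(sid)
        if z == 1 and p == 0 and d == direction_bit:
            w[sid] = 1.0
    return w


def _spot_weights_small_bright() -> np.ndarray:
    """Small, bright spots (any direction/speed) -- rarely trigger hunting."""
    w = np.zeros(N_SPOT_STIMULI)
    for sid in range(N_SPOT_STIMULI):
        d, s, z, p = feature_code(sid)
        if z == 0 and p == 0:
            w[sid] = 1.0
    return w


def generate_population(
    geometry: Optional[GeometryParams] = None,
    mixture_weights: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[ROIRecord], GroundTruth]:
    """Plant a labelled ROI population in the region map.

    ``mixture_weights`` must sum to 1 over archetype names; counts are the
    rounded expectation per archetype (assembly cells are allocated in whole
    assemblies).  The same seed always regenerates the identical population.
    """
    if geometry is None:
        geometry = GeometryParams()
    if mixture_weights is None:
        mixture_weights = dict(DEFAULT_MIXTURE)
    total = sum(mixture_weights.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mixture weights must sum to 1 (got {total})")
    rmap = geometry.region_map
    rmap.validate()
    if not rmap.regions:
        raise ValueError("region map has no regions")

    rng = np.random.default_rng(seed)
    regressors = build_regressors()

    rois: list[ROIRecord] = []
    truth = GroundTruth(seed=seed)
    next_id = 0

    def _place(region: str, archetype: str, fish_id: int, **cell_kw) -> None:
        nonlocal next_id
        x, y = rmap.sample_point(region, rng, margin=2.0)
        roi = ROIRecord.from_point(next_id, x, y, rmap, fish_id=fish_id)
        rois.append(roi)
        truth.cells[next_id] = CellTruth(roi_id=next_id, archetype=archetype, **cell_kw)
        next_id += 1

    n_total = geometry.n_rois
    counts = {k: int(round(v * n_total)) for k, v in mixture_weights.items()}
    amp = lambda: float(rng.lognormal(mean=0.0, sigma=0.25))

    # --- assemblies (whole groups) -------------------------------------
    n_assembly_cells = counts.pop("assembly", 0)
    lo, hi = geometry.assembly_size_range
    a_id = 0
    while n_assembly_cells >= lo:
        size = int(rng.integers(lo, min(hi, n_assembly_cells) + 1))
        hemi = "L" if a_id % 2 == 0 else "R"
        region = f"OTc-SPV-{hemi}"
        cx, cy = rmap.sample_point(region, rng, margin=4 * geometry.assembly_scale_um)
        lead = int(rng.integers(*geometry.assembly_lead_range))
        fish = int(rng.integers(geometry.n_fish))
        members = []
        for _ in range(size):
            for _try in range(100):
                x = cx + rng.normal(0, geometry.assembly_scale_um)
                y = cy + rng.normal(0, geometry.assembly_scale_um)
                if rmap.lookup(x, y) == region:
                    break
            roi = ROIRecord.from_point(next_id, x, y, rmap, fish_id=fish)
            rois.append(roi)
            # weak, heterogeneous visual tuning: each member responds to one
            # random small bright spot, so members register as visually
            # responsive, yet the stimuli that trigger hunting (large dark)
            # leave their response trials clean of visual drive and the
            # members share no coherent visual co-activation
            w = np.zeros(N_SPOT_STIMULI)
            sb = np.flatnonzero(_spot_weights_small_bright())
            w[rng.choice(sb)] = 0.5
            truth.cells[next_id] = CellTruth(
                roi_id=next_id,
                archetype="assembly",
                amplitude=amp(),
                w16=w,
                rf_azimuth=float(rng.uniform(-60.0, 60.0)),
                assembly_id=a_id,
            )
            members.append(next_id)
            next_id += 1
        truth.assemblies.append(
            AssemblyTruth(
                assembly_id=a_id,
                hemisphere=hemi,
                member_roi_ids=members,
                lead_frames=lead,
                center=(cx, cy),
            )
        )
        n_assembly_cells -= size
        a_id += 1

    # --- single-cell archetypes ----------------------------------------
    for archetype, n in counts.items():
        for _ in range(n):
            fish = int(rng.integers(geometry.n_fish))
            if archetype == "nonresponsive":
                region = rng.choice(list(rmap.regions))
                _place(region, archetype, fish)
            elif archetype == "lum_on":
                region = (
                    "TL"
                    if rng.random() < geometry.on_tl_fraction
                    else rng.choice(["Hb-L", "Hb-R", "OTc-SPV-L", "OTc-SPV-R"])
                )
                _place(
                    region, archetype, fish,
                    amplitude=amp(), lum_gain=1.0,
                    w16=_spot_weights_bright_ds(0) + _spot_weights_bright_ds(1),
                )
            elif archetype == "lum_dimming":
                region = rng.choice(["TL", "OTc-SPV-L", "OTc-SPV-R"])
                _place(region, archetype, fish, amplitude=amp(), dimming_gain=1.0)
            elif archetype == "lum_inhibited":
                region = rng.choice(["Hb-L", "Hb-R", "TL", "OTc-SPV-L", "OTc-SPV-R"])
                _place(region, archetype, fish, amplitude=amp(), lum_gain=-0.7)
            elif archetype in SPOT_CLUSTER_ARCHETYPES:
                # mirror pairs: retinotectal input is fully crossed, so the
                # left tectum sees the right visual hemifield
                d_bit = 0 if "RL" in archetype else 1
                hemi = "L" if archetype.endswith("left") else "R"
                rf = rng.normal(35.0, 8.0) if hemi == "L" else rng.normal(-35.0, 8.0)
                _place(
                    f"OTc-SPV-{hemi}", archetype, fish,
                    amplitude=amp(),
                    w16=_spot_weights_bright_ds(d_bit),
                    rf_azimuth=float(np.clip(rf, -80, 80)),
                )
            elif archetype in NLMS_ARCHETYPES:
                key = archetype.removeprefix("nlms_")
                hemi = "L" if rng.random() < 0.5 else "R"
                rf = float(np.clip(rng.normal(-5.6, 15.0), -60, 60))
                _place(
                    f"OTc-SPV-{hemi}", archetype, fish,
                    amplitude=amp(), w16=regressors[key].copy(), rf_azimuth=rf,
                )
            else:
                raise ValueError(f"unknown archetype '{archetype}'")

    return rois, truth
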
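"""IIR-driven tissue remodeling rules and ablation-mask construction.

Translates fibrosis intensity (IIR) into the parameters the monodomain solver
consumes:

* structural remodeling — piecewise-constant tissue conductivity bins
  calibrated against planar conduction velocities
  (0.40 / 0.31 / 0.28 / 0.19 S/m for CVs 0.81 / 0.74 / 0.71 / 0.58 m/s);
* electrophysiological remodeling — multiplicative rescalings of the maximal
  Courtemanche conductances, composed from three layers: a global baseline
  (gNa x2 for physiological upstroke, gK1 x0.8 for restitution agreement),
  AF electrical remodeling (Ito x0.5, IKur x0.5, ICaL x0.3) and, above a
  fibrosis threshold, TGF-beta1-like fibrotic remodeling
  (gK1 x0.5, gNa x0.6, gCaL x0.5);
* the four ablation strategies as boolean non-conducting masks: PVI rings on
  the LA always, plus fibrosis ablation (IIR > 1.22) in the LA and/or RA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .maps import FIBROSIS_THRESHOLD_IIR, FibrosisMap

#: Conductivity bin edges in IIR and values in S/m (left-closed bins; the
#: boundary pixel joins the higher-fibrosis bin so the mapping is total).
CONDUCTIVITY_BIN_EDGES = (0.9, 1.4, 1.6)
CONDUCTIVITY_VALUES_S_PER_M = (0.40, 0.31, 0.28, 0.19)
#: Target planar CVs (m/s) for the four bins, used for calibration checks.
CONDUCTIVITY_CV_TARGETS_M_PER_S = (0.81, 0.74, 0.71, 0.58)

#: IIR threshold above which fibrotic EP remodeling applies (reuses the
#: ablation-mask threshold; the remodeling threshold itself is a free choice).
EP_REMODELING_THRESHOLD_IIR = FIBROSIS_THRESHOLD_IIR


class AblationStrategy(enum.Enum):
    """The four ablation strategies, in the fixed order used everywhere
    (cohort records, classifier outputs, ground-truth labels)."""

    PVI = "PVI"
    PVI_LA = "PVI+LA"
    PVI_RA = "PVI+RA"
    PVI_LA_RA = "PVI+LA+RA"

    @property
    def includes_la_fibrosis(self) -> bool:
        return self in (AblationStrategy.PVI_LA, AblationStrategy.PVI_LA_RA)

    @property
    def includes_ra_fibrosis(self) -> bool:
        return self in (AblationStrategy.PVI_RA, AblationStrategy.PVI_LA_RA)


STRATEGY_ORDER = (
    AblationStrategy.PVI,
    AblationStrategy.PVI_LA,
    AblationStrategy.PVI_RA,
    AblationStrategy.PVI_LA_RA,
)


@dataclass(frozen=True)
class IonicScaling:
    """Multipliers applied to the base Courtemanche maximal conductances."""

    g_Na: float = 1.0
    g_K1: float = 1.0
    g_to: float = 1.0
    g_Kur: float = 1.0
    g_CaL: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K1", "g_to", "g_Kur", "g_CaL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} multiplier must be > 0")

    def compose(self, other: "IonicScaling") -> "IonicScaling":
        return IonicScaling(
            self.g_Na * other.g_Na,
            self.g_K1 * other.g_K1,
            self.g_to * other.g_to,
            self.g_Kur * other.g_Kur,
            self.g_CaL * other.g_CaL,
        )


#: Baseline modifications applied everywhere (upstroke velocity / restitution).
BASELINE_SCALING = IonicScaling(g_Na=2.0, g_K1=0.8)
#: AF electrical remodeling, applied in all regions when AF remodeling is on.
AF_REMODELING_SCALING = IonicScaling(g_to=0.5, g_Kur=0.5, g_CaL=0.3)
#: Fibrotic EP remodeling, applied where IIR exceeds the fibrosis threshold.
FIBROTIC_SCALING = IonicScaling(g_K1=0.5, g_Na=0.6, g_CaL=0.5)


def conductivity_from_iir(iir):
    """Piecewise-constant structural-remodeling conductivity (S/m) for IIR.

    [0, 0.9) -> 0.40, [0.9, 1.4) -> 0.31, [1.4, 1.6) -> 0.28, [1.6, inf) -> 0.19.
    Accepts scalars or arrays.
    """
    arr = np.asarray(iir, dtype=float)
    if np.any(arr < 0):
        raise ValueError("IIR must be non-negative")
    idx = np.searchsorted(CONDUCTIVITY_BIN_EDGES, arr, side="right")
    out = np.asarray(CONDUCTIVITY_VALUES_S_PER_M)[idx]
    return float(out) if np.isscalar(iir) else out


def ionic_scaling_for(
    iir: float,
    af_remodeling_on: bool = True,
    fibrotic_threshold: float = EP_REMODELING_THRESHOLD_IIR,
) -> IonicScaling:
    """Compose the ionic-conductance multipliers for a pixel of given IIR."""
    if iir < 0:
        raise ValueError("IIR must be non-negative")
    scaling = BASELINE_SCALING
    if af_remodeling_on:
        scaling = scaling.compose(AF_REMODELING_SCALING)
    if iir > fibrotic_threshold:
        scaling = scaling.compose(FIBROTIC_SCALING)
    return scaling


def ionic_scaling_fields(
    iir_map: np.ndarray,
    af_remodeling_on: bool = True,
    fibrotic_threshold: float = EP_REMODELING_THRESHOLD_IIR,
) -> dict[str, np.ndarray]:
    """Vectorized per-node multiplier fields for the five scaled conductances."""
    base = BASELINE_SCALING.compose(AF_REMODELING_SCALING) if af_remodeling_on \
        else BASELINE_SCALING
    fib = base.compose(FIBROTIC_SCALING)
    mask = np.asarray(iir_map) > fibrotic_threshold
    out = {}
    for name in ("g_Na", "g_K1", "g_to", "g_Kur", "g_CaL"):
        out[name] = np.where(mask, getattr(fib, name), getattr(base, name))
    return out


# ---------------------------------------------------------------------------
# Ablation masks
# ---------------------------------------------------------------------------

@dataclass
class PviRingConfig:
    """PVI ring geometry on the unfolded LA sheet (unit coordinates).

    Two annuli stand in for the left and right pulmonary-vein antra; the
    interior of each antrum stays conducting but is electrically isolated by
    the non-conducting ring.
    """

    centers: tuple[tuple[float, float], ...] = ((0.2, 0.8), (0.8, 0.8))
    radius: float = 0.12
    width_px: float = 2.0
    enabled: bool = True


def pvi_ring_mask(shape: tuple[int, int], config: PviRingConfig | None = None) -> np.ndarray:
    """Boolean mask of the PVI rings on a grid of the given shape."""
    config = config or PviRingConfig()
    mask = np.zeros(shape, dtype=bool)
    if not config.enabled:
        return mask
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    # unit coordinates of pixel centers; x = column, y = row
    xu = (x + 0.5) / nx
    yu = (y + 0.5) / ny
    half_w = config.width_px / (2.0 * min(nx, ny))
    for cx, cy in config.centers:
        r = np.hypot(xu - cx, yu - cy)
        mask |= np.abs(r - config.radius) <= half_w
    return mask


def fibrosis_ablation_mask(
    fmap: FibrosisMap | np.ndarray,
    threshold: float = FIBROSIS_THRESHOLD_IIR,
) -> np.ndarray:
    """Pixels targeted by fibrosis ablation: IIR strictly above the threshold."""
    values = fmap.values if isinstance(fmap, FibrosisMap) else np.asarray(fmap)
    return values > threshold


def build_ablation_masks(
    la_map: FibrosisMap | np.ndarray,
    ra_map: FibrosisMap | np.ndarray,
    strategy: AblationStrategy,
    threshold: float = FIBROSIS_THRESHOLD_IIR,
    ring_config: PviRingConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (LA, RA) non-conducting masks for one ablation strategy.

    The LA mask always contains the PVI rings, plus the fibrotic pixels when
    the strategy includes LA fibrosis ablation.  The RA mask contains the
    fibrotic pixels when the strategy includes RA fibrosis ablation and is
    all-zero otherwise (PVI itself involves no RA lesions).
    """
    if not isinstance(strategy, AblationStrategy):
        raise ValueError(f"unknown strategy {strategy!r}")
    la = la_map.values if isinstance(la_map, FibrosisMap) else np.asarray(la_map)
    ra = ra_map.values if isinstance(ra_map, FibrosisMap) else np.asarray(ra_map)
    la_mask = pvi_ring_mask(la.shape, ring_config)
    if strategy.includes_la_fibrosis:
        la_mask = la_mask | fibrosis_ablation_mask(la, threshold)
    ra_mask = np.zeros(ra.shape, dtype=bool)
    if strategy.includes_ra_fibrosis:
        ra_mask = fibrosis_ablation_mask(ra, threshold)
    return la_mask, ra_mask
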
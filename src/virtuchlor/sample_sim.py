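"""Synthetic optical samples and the field sampling designs.

Leaves are modelled with a per-band decadic Beer–Lambert law: chlorophyll
adds absorbance only in the red band (where its extinction is strong) while
the NIR reference band sees only the pigment-free structural baseline, so

    T_red = 10^-(A_red,baseline + eps_red * chl)
    T_nir = 10^-(A_nir,baseline)

and the device index M = log10(T_nir/T_red) is affine in the chlorophyll
amount — which gives every downstream test a closed-form expectation.
Colour filters are near-uniform transmittance pairs.  The sampling designs
mirror the acquisition campaigns: 30 lemon-tree leaves x 5 areas x 5
repeats (leaves spanning premature to dry stages, a wide greenness range),
32 young Brussels-sprouts leaves x 3 areas x 5 repeats (a narrow range),
and filter panels of 9 green (plus optionally 4 blue) filters x 10
positions x 5 repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration_stats import ConversionModel
from .meter_core import AirReference, Instrument, scan

__all__ = [
    "LeafModel",
    "FilterModel",
    "SamplingDesign",
    "OpticalSample",
    "DESIGNS",
    "DEFAULT_CHL_RANGE",
    "band_transmittance",
    "draw_leaf_areas",
    "make_leaf_panel",
    "make_filter_panel",
    "simulate_paired_readings",
]

# Default leaf optics: specific red absorbance 1 per chlorophyll unit, a thin
# structural red baseline and an NIR baseline of 0.30 decades (leaves transmit
# roughly half the incident NIR).  With these, M = chl - 0.29, so the wide
# default chlorophyll range below maps onto device outputs -0.29..0.92, the
# span observed across premature-to-dry lemon leaves.
DEFAULT_CHL_RANGE: Tuple[float, float] = (0.0, 1.21)


@dataclass(frozen=True)
class OpticalSample:
    """A scalar band-transmittance pair, directly scannable by the instrument."""

    t_red: float
    t_nir: float


@dataclass(frozen=True)
class LeafModel:
    """Beer–Lambert leaf: chlorophyll absorbs red, NIR sees only the baseline."""

    chl_index: float
    red_specific_absorbance: float = 1.0
    baseline_absorbance_red: float = 0.01
    baseline_absorbance_nir: float = 0.30
    heterogeneity_sd: float = 0.02
    thickness: float = 0.3
    label: str = "leaf"

    def __post_init__(self) -> None:
        if self.chl_index < 0.0:
            raise ValueError("chl_index must be non-negative")
        if min(
            self.red_specific_absorbance,
            self.baseline_absorbance_red,
            self.baseline_absorbance_nir,
        ) < 0.0:
            raise ValueError("absorbances must be non-negative")
        if self.thickness > 1.5:
            raise ValueError("leaf thickness exceeds the 1.5 mm clip limit")


@dataclass(frozen=True)
class FilterModel:
    """Colour filter: near-uniform band transmittances across its surface.

    ``reference_bias`` optionally offsets the emulated reference-meter
    readings (target units); it models a filter whose spectrum interacts
    differently with a reference meter's slightly different LED bands,
    producing an off-trend outlier like the dark-blue filter.
    """

    label: str
    t_red: float
    t_nir: float
    uniformity_sd: float = 0.004
    thickness: float = 0.3
    reference_bias: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t_red <= 1.0 and 0.0 < self.t_nir <= 1.0):
            raise ValueError("filter transmittances must lie in (0, 1]")
        if self.uniformity_sd < 0.0:
            raise ValueError("uniformity_sd must be non-negative")


@dataclass(frozen=True)
class SamplingDesign:
    """samples x areas x repeats measurement grid."""

    n_samples: int
    areas_per_sample: int
    repeats_per_area: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.areas_per_sample, self.repeats_per_area) < 1:
            raise ValueError("all design counts must be >= 1")


# The three acquisition campaigns.
DESIGNS: dict[str, SamplingDesign] = {
    "lemon30": SamplingDesign(n_samples=30, areas_per_sample=5),
    "sprouts32": SamplingDesign(n_samples=32, areas_per_sample=3),
    "filters": SamplingDesign(n_samples=9, areas_per_sample=10),
}


def band_transmittance(leaf: LeafModel, area_chl: float) -> Tuple[float, float]:
    """Band transmittances of one leaf area with the given chlorophyll amount."""
    if area_chl < 0.0:
        raise ValueError("area chlorophyll must be non-negative")
    t_red = 10.0 ** -(
        leaf.baseline_absorbance_red + leaf.red_specific_absorbance * area_chl
    )
    t_nir = 10.0 ** -(leaf.baseline_absorbance_nir)
    return (min(t_red, 1.0), min(t_nir, 1.0))


def draw_leaf_areas(
    leaf: LeafModel, design: SamplingDesign, rng: np.random.Generator
) -> np.ndarray:
    """Per-area chlorophyll values: N(chl_index, heterogeneity_sd²), floored at 0."""
    draws = rng.normal(leaf.chl_index, leaf.heterogeneity_sd, design.areas_per_sample)
    return np.maximum(draws, 0.0)


def make_leaf_panel(
    n: int,
    chl_range: Tuple[float, float] = DEFAULT_CHL_RANGE,
    stage_profile: str = "wide",
    rng: Optional[np.random.Generator] = None,
    **leaf_kwargs,
) -> List[LeafModel]:
    """A panel of leaves spanning a development-stage chlorophyll range.

    ``wide`` draws uniformly over ``chl_range`` (mixed stages, premature to
    dry, as in the lemon-tree set); ``young`` draws from the central third
    (a same-age cohort, as in the Brussels-sprouts set).
    """
    low, high = chl_range
    if not low < high:
        raise ValueError("chl_range must satisfy low < high")
    if n < 2:
        raise ValueError("a calibration panel needs at least 2 leaves")
    rng = np.random.default_rng() if rng is None else rng
    if stage_profile == "wide":
        chls = rng.uniform(low, high, n)
    elif stage_profile == "young":
        third = (high - low) / 3.0
        chls = rng.uniform(low + third, high - third, n)
    else:
        raise ValueError("stage_profile must be 'wide' or 'young'")
    return [
        LeafModel(chl_index=float(c), label=f"leaf-{i + 1}", **leaf_kwargs)
        for i, c in enumerate(chls)
    ]


def _filter_from_index(label: str, m_target: float, t_nir: float, **kwargs) -> FilterModel:
    """Build a filter whose noise-free device output is ``m_target``."""
    t_red = t_nir / 10.0**m_target
    return FilterModel(label=label, t_red=t_red, t_nir=t_nir, **kwargs)


def make_filter_panel(
    preset: str = "green9", rng: Optional[np.random.Generator] = None
) -> List[FilterModel]:
    """Built-in colour-filter panels.

    ``green9``: nine green filters whose device outputs spread over roughly
    0.02..0.82 (green gels pass more NIR than red, so all outputs are
    positive).  ``all13`` adds four blue filters at the low end of the range
    (down to about −0.09), one of them a dark-blue outlier whose emulated
    reference readings sit off the common affine trend.
    """
    greens = [
        _filter_from_index(f"green-{i + 1}", m, t_nir=0.70)
        for i, m in enumerate(np.linspace(0.02, 0.82, 9))
    ]
    if preset == "green9":
        return greens
    if preset == "all13":
        blues = [
            _filter_from_index("blue-1", -0.09, t_nir=0.35),
            _filter_from_index("blue-2", -0.04, t_nir=0.35),
            _filter_from_index("blue-3", 0.06, t_nir=0.30),
            _filter_from_index("blue-4-dark", 0.00, t_nir=0.20, reference_bias=-6.0),
        ]
        return greens + blues
    raise ValueError("preset must be 'green9' or 'all13'")


def _area_sample(
    model: Union[LeafModel, FilterModel],
    rng: np.random.Generator,
) -> Tuple[OpticalSample, float]:
    """Draw one measurement area; returns its optics and the reference bias."""
    if isinstance(model, LeafModel):
        chl = max(float(rng.normal(model.chl_index, model.heterogeneity_sd)), 0.0)
        t_red, t_nir = band_transmittance(model, chl)
        return OpticalSample(t_red, t_nir), 0.0
    t_red = float(np.clip(rng.normal(model.t_red, model.uniformity_sd), 1e-6, 1.0))
    t_nir = float(np.clip(rng.normal(model.t_nir, model.uniformity_sd), 1e-6, 1.0))
    return OpticalSample(t_red, t_nir), model.reference_bias


def simulate_paired_readings(
    panel: Sequence[Union[LeafModel, FilterModel]],
    design: SamplingDesign,
    instrument: Instrument,
    air: AirReference,
    reference_conversions: Sequence[ConversionModel],
    rng: np.random.Generator,
    reference_noise_sd: float = 3.0,
) -> pd.DataFrame:
    """Measure a panel with the virtual device and emulated reference meters.

    For each sample x area, the device performs ``repeats_per_area`` scans
    of the same spot (only detector noise varies between repeats).  The
    reference meters are emulated by applying each ConversionModel to the
    noise-free index of that area and adding Gaussian noise of
    ``reference_noise_sd`` (target units per repeat) — covering both the
    meters' own noise and the spot mismatch from re-clipping three
    instruments on "approximately the same position".

    Returns a tidy table with one row per (sample, area, repeat):
    sample_id, area_id, repeat, V_red, V_ir, T_red, T_ir, M, and one column
    per reference target ("spad"/"atleaf").
    """
    if len(panel) != design.n_samples:
        raise ValueError(
            f"panel size {len(panel)} does not match design n_samples "
            f"{design.n_samples}"
        )
    rows = []
    for si, model in enumerate(panel, start=1):
        for ai in range(1, design.areas_per_sample + 1):
            area, bias = _area_sample(model, rng)
            m_true = math.log10(area.t_nir / area.t_red)
            for rep in range(1, design.repeats_per_area + 1):
                result = scan(area, air, instrument, rng)
                row = {
                    "sample_id": getattr(model, "label", f"sample-{si}"),
                    "area_id": ai,
                    "repeat": rep,
                    "V_red": result.v_red,
                    "V_ir": result.v_ir,
                    "T_red": result.t_red,
                    "T_ir": result.t_ir,
                    "M": result.m,
                }
                for conv in reference_conversions:
                    noise = (
                        rng.normal(0.0, reference_noise_sd)
                        if reference_noise_sd > 0.0
                        else 0.0
                    )
                    row[conv.target] = conv.convert(m_true) + bias + noise
                rows.append(row)
    return pd.DataFrame(rows)
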
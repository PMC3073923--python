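"""Synthetic CSMA ground truth: per-spot cell populations and rendered images.

The generator emulates the statistical structure the Ki-67/cPARP spot assay
relies on:

* spot-confined cell counts, rounded-Normal with the reference means
  (51 +/- 3 cells on a 200 um spot, 151 +/- 8 on 400 um, 21 +/- 6 for slow
  stromal cultures);
* integrated nuclear DAPI intensity proportional to DNA content (2N in G1/S,
  4N in G2 and M) with multiplicative lognormal cell-to-cell variation;
* nuclear Ki-67 rising monotonically G1/S < G2 < M in cycling cells;
* cleaved PARP rising with apoptotic progression, mutually exclusive with
  high Ki-67 (apoptotic cells drop to a Ki-67-negative background level);
* mitotic chromatin condensation (smaller nuclear area, hence much higher
  mean DAPI at conserved integrated intensity);
* optional TuGFP cytoplasmic signal knocked down in transfected cells;
* per-(array, pin, channel) multiplicative intensity bias;
* per-sample effects shared between replicate arrays.

All intensities are in arbitrary fluorescence units.  Every stochastic output
is reproducible from (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, PackingError
from .layout import CONTROL_ID, EMPTY_ID, ArrayLayout

PHASES = ("G1S", "G2", "M")
NUCLEAR_CHANNELS = ("dapi", "ki67", "cparp")


@dataclass(frozen=True)
class IntensityModel:
    """Per-cell intensity and geometry model (arbitrary fluorescence units).

    ``dapi_integrated_2n`` fixes the integrated (area-summed, at
    ``ref_pixel_size_um`` sampling) DAPI intensity of a 2N nucleus; mean
    intensity follows from the nuclear area.  Antibody channels are specified
    as nuclear mean intensities.  ``intensity_cv`` is the biological
    cell-to-cell lognormal coefficient of variation applied per channel.
    """

    dapi_integrated_2n: float = 1.2e5
    intensity_cv: float = 0.15
    ki67_phase_means: tuple[float, float, float] = (400.0, 640.0, 880.0)
    ki67_negative_mean: float = 120.0
    cparp_baseline_mean: float = 100.0
    cparp_apoptotic_fold: tuple[float, float] = (2.0, 10.0)
    tugfp_cyto_mean: float = 300.0
    radius_2n_um: float = 5.0
    radius_cv: float = 0.07
    # nuclear radius scale per phase: G2 nuclei grow, mitotic chromatin condenses
    radius_scale: tuple[float, float, float] = (1.0, 1.1, 0.7)
    ref_pixel_size_um: float = 0.65


DEFAULT_MODEL = IntensityModel()


@dataclass
class SpotTruth:
    """Planted ground truth for one spot population."""

    spot_id: int = 0
    mean_cells: float = 51.0
    sd_cells: float = 3.0
    spot_diameter_um: float = 200.0
    knockdown_frac: float = 0.0
    transfection_frac: float = 0.9
    apoptosis_frac: float = 0.05
    cycle_probs: tuple[float, float, float] = (0.65, 0.28, 0.07)
    ki67_scale: float = 1.0
    cparp_scale: float = 1.0
    pin_bias: Mapping[str, float] | None = None
    sample_id: str = CONTROL_ID
    pin_id: int = 0

    def __post_init__(self) -> None:
        if self.mean_cells < 0 or self.sd_cells < 0:
            raise ValueError("mean_cells and sd_cells must be >= 0")
        for name in ("knockdown_frac", "transfection_frac", "apoptosis_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.cycle_probs) - 1.0) > 1e-9:
            raise ValueError("cycle_probs must sum to 1")


@dataclass
class FieldImage:
    """Multichannel raster of one imaged spot.

    ``origin_um`` is the physical coordinate of the center of pixel (0, 0)
    in the layout frame (+x columns, +y rows).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    spot_id: int = 0
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _place_cells(
    rng: np.random.Generator,
    radii: np.ndarray,
    spot_radius_um: float,
    enforce_spacing: bool,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform positions in the spot disk; optional non-overlap rejection."""
    n = len(radii)
    if n == 0:
        return np.empty((0, 2))
    if not enforce_spacing:
        r = (spot_radius_um - radii.clip(max=spot_radius_um)) * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pos = np.empty((n, 2))
    for i in range(n):
        rmax = max(spot_radius_um - radii[i], 0.0)
        for _ in range(max_tries):
            rad = rmax * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            cand = np.array([rad * math.cos(th), rad * math.sin(th)])
            if i == 0:
                pos[0] = cand
                break
            d = np.hypot(*(pos[:i] - cand).T)
            if np.all(d >= radii[:i] + radii[i]):
                pos[i] = cand
                break
        else:
            raise PackingError(
                f"could not place {n} non-overlapping nuclei in a "
                f"{2 * spot_radius_um:.0f} um spot"
            )
    return pos


def simulate_spot_cells(
    truth: SpotTruth,
    seed: int | np.random.Generator = 0,
    model: IntensityModel = DEFAULT_MODEL,
    enforce_spacing: bool = True,
) -> pd.DataFrame:
    """Draw one spot's cell population with latent states and true intensities.

    Returns one row per cell with columns: ``cell_id, x_um, y_um`` (relative
    to the spot center), ``radius_um, phase, apoptotic, transfected,
    progression``, plus true (noise-free pixel, biology-noisy) channel levels
    ``dapi_int_true`` (integrated) and ``ki67_mean_true, cparp_mean_true,
    tugfp_mean_true`` (nuclear / cytoplasmic means).

    The cell count is a rounded Normal(mean_cells, sd_cells) truncated at 0;
    ``sd_cells = 0`` yields exactly ``mean_cells`` cells.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(max(0, round(rng.normal(truth.mean_cells, truth.sd_cells)))) if truth.sd_cells > 0 else int(round(truth.mean_cells))

    phase_idx = rng.choice(3, size=n, p=np.asarray(truth.cycle_probs, dtype=float))
    apoptotic = rng.uniform(size=n) < truth.apoptosis_frac
    transfected = rng.uniform(size=n) < truth.transfection_frac
    progression = rng.uniform(size=n)

    content = np.where(phase_idx == 0, 1.0, 2.0)  # 2N vs 4N DNA
    radius = (
        model.radius_2n_um
        * np.asarray(model.radius_scale)[phase_idx]
        * _lognormal_factors(rng, model.radius_cv, n)
    )
    dapi_int = model.dapi_integrated_2n * content * _lognormal_factors(rng, model.intensity_cv, n)

    ki67 = np.asarray(model.ki67_phase_means)[phase_idx] * truth.ki67_scale
    ki67 = np.where(apoptotic, model.ki67_negative_mean, ki67)
    ki67 = ki67 * _lognormal_factors(rng, model.intensity_cv, n)

    lo, hi = model.cparp_apoptotic_fold
    cparp = np.where(
        apoptotic,
        model.cparp_baseline_mean * (lo + (hi - lo) * progression) * truth.cparp_scale,
        model.cparp_baseline_mean,
    )
    cparp = cparp * _lognormal_factors(rng, model.intensity_cv, n)

    tugfp = model.tugfp_cyto_mean * np.where(transfected, 1.0 - truth.knockdown_frac, 1.0)
    tugfp = tugfp * _lognormal_factors(rng, model.intensity_cv, n)

    pos = _place_cells(rng, radius, truth.spot_diameter_um / 2.0, enforce_spacing)

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "radius_um": radius,
            "phase": np.asarray(PHASES)[phase_idx],
            "apoptotic": apoptotic,
            "transfected": transfected,
            "progression": progression,
            "dapi_int_true": dapi_int,
            "ki67_mean_true": ki67,
            "cparp_mean_true": cparp,
            "tugfp_mean_true": tugfp,
        }
    )


def truth_to_records(
    cells: pd.DataFrame,
    truth: SpotTruth,
    pixel_size_um: float = DEFAULT_MODEL.ref_pixel_size_um,
    spot_center_um: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Convert a spot's cell truth into a measured-style CellRecord table.

    This is the "tables" simulation mode: per-cell features as the imaging
    stage would report them, bypassing rendering and segmentation.  Pin bias
    (if present in ``truth.pin_bias``) is applied multiplicatively per
    channel, as a staining/printing artifact would act on the raw images.
    """
    bias = dict(truth.pin_bias or {})
    area_um2 = np.pi * cells["radius_um"].to_numpy() ** 2
    area_px = area_um2 / pixel_size_um**2
    dapi_mean = bias.get("dapi", 1.0) * cells["dapi_int_true"].to_numpy() / area_px
    ki67_mean = bias.get("ki67", 1.0) * cells["ki67_mean_true"].to_numpy()
    cparp_mean = bias.get("cparp", 1.0) * cells["cparp_mean_true"].to_numpy()
    tugfp_ring = bias.get("tugfp", 1.0) * cells["tugfp_mean_true"].to_numpy()
    x = spot_center_um[0] + cells["x_um"].to_numpy()
    y = spot_center_um[1] + cells["y_um"].to_numpy()
    return pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "spot_id": truth.spot_id,
            "sample_id": truth.sample_id,
            "pin_id": truth.pin_id,
            "x_um": x,
            "y_um": y,
            "nuclear_area_px": area_px,
            "nuclear_area_um2": area_um2,
            "dapi_mean": dapi_mean,
            "dapi_int": dapi_mean * area_px,
            "ki67_mean": ki67_mean,
            "ki67_int": ki67_mean * area_px,
            "cparp_mean": cparp_mean,
            "cparp_int": cparp_mean * area_px,
            "tugfp_ring_mean": tugfp_ring,
            "distance_to_spot_center_um": np.hypot(
                cells["x_um"].to_numpy(), cells["y_um"].to_numpy()
            ),
            "excluded": False,
        }
    )


def render_spot_image(
    cells: pd.DataFrame,
    pixel_size_um: float = DEFAULT_MODEL.ref_pixel_size_um,
    noise_sd: float = 20.0,
    background: float = 100.0,
    seed: int | np.random.Generator = 0,
    spot_diameter_um: float = 200.0,
    cyto_width_um: float = 10.0,
    blur_sigma_um: float = 0.5,
    pin_bias: Mapping[str, float] | None = None,
    spot_id: int = 0,
    spot_center_um: tuple[float, float] = (0.0, 0.0),
) -> FieldImage:
    """Render a cell population as a multichannel fluorescence image.

    Nuclei are drawn as disks carrying their nuclear channel levels (DAPI
    pixel value = integrated intensity / nuclear pixel area, so integration is
    conserved), a cytoplasmic annulus of ``cyto_width_um`` carries the TuGFP
    mean, and the stack is lightly blurred, offset by a uniform ``background``,
    degraded with additive Gaussian noise of ``noise_sd`` and clipped at 0.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bias = dict(pin_bias or {})

    half_um = spot_diameter_um / 2.0 + cyto_width_um + 8.0
    if len(cells):
        half_um = max(
            half_um,
            float(np.max(np.hypot(cells["x_um"], cells["y_um"]) + cells["radius_um"]))
            + cyto_width_um
            + 8.0,
        )
    half_px = int(math.ceil(half_um / pixel_size_um))
    size = 2 * half_px + 1
    yy, xx = np.mgrid[0:size, 0:size]
    xg = (xx - half_px) * pixel_size_um
    yg = (yy - half_px) * pixel_size_um

    imgs = {ch: np.zeros((size, size)) for ch in ("dapi", "ki67", "cparp", "tugfp")}
    for row in cells.itertuples(index=False):
        r_px = max(1, int(math.ceil((row.radius_um + cyto_width_um) / pixel_size_um)) + 1)
        cx = half_px + int(round(row.x_um / pixel_size_um))
        cy = half_px + int(round(row.y_um / pixel_size_um))
        sl = (
            slice(max(cy - r_px, 0), min(cy + r_px + 1, size)),
            slice(max(cx - r_px, 0), min(cx + r_px + 1, size)),
        )
        d = np.hypot(xg[sl] - row.x_um, yg[sl] - row.y_um)
        nuc = d <= row.radius_um
        n_px = max(int(nuc.sum()), 1)
        imgs["dapi"][sl][nuc] += row.dapi_int_true / n_px
        imgs["ki67"][sl][nuc] += row.ki67_mean_true
        imgs["cparp"][sl][nuc] += row.cparp_mean_true
        ring = (d > row.radius_um) & (d <= row.radius_um + cyto_width_um)
        patch = imgs["tugfp"][sl]
        patch[ring] = np.maximum(patch[ring], row.tugfp_mean_true)

    sigma_px = blur_sigma_um / pixel_size_um
    for ch, img in imgs.items():
        img *= bias.get(ch, 1.0)
        if sigma_px > 0:
            img = gaussian_filter(img, sigma_px)
        img = img + background
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        imgs[ch] = np.clip(img, 0.0, None)

    origin = (
        spot_center_um[0] - half_px * pixel_size_um,
        spot_center_um[1] - half_px * pixel_size_um,
    )
    return FieldImage(channels=imgs, pixel_size_um=pixel_size_um, spot_id=spot_id, origin_um=origin)


# ---------------------------------------------------------------------------
# Whole-screen simulation
# ---------------------------------------------------------------------------

EFFECT_COLUMNS = (
    "ki67_scale",
    "cparp_scale",
    "apoptosis_frac",
    "knockdown_frac",
    "count_scale",
    "transfection_frac",
)


def null_effects(sample_ids: Sequence[str]) -> pd.DataFrame:
    """An effect table with no planted phenotype for every sample."""
    df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    df["ki67_scale"] = 1.0
    df["cparp_scale"] = 1.0
    df["apoptosis_frac"] = np.nan  # NaN = keep the baseline default
    df["knockdown_frac"] = 0.0
    df["count_scale"] = 1.0
    df["transfection_frac"] = np.nan
    return df


@dataclass
class ScreenSim:
    """Output of :func:`simulate_screen`."""

    cells: pd.DataFrame
    spot_truth: pd.DataFrame
    cell_truth: pd.DataFrame
    images: dict[tuple[int, int], FieldImage] | None = None


def simulate_screen(
    layout: ArrayLayout,
    effects: pd.DataFrame,
    n_replicates: int = 2,
    replicate_noise: float = 0.0,
    sample_effect_sd: float = 0.0,
    seed: int = 0,
    mode: str = "tables",
    model: IntensityModel = DEFAULT_MODEL,
    base_truth: SpotTruth | None = None,
    pixel_size_um: float = DEFAULT_MODEL.ref_pixel_size_um,
    pin_bias_range: tuple[float, float] = (0.8, 1.25),
    noise_sd: float = 20.0,
    background: float = 100.0,
) -> ScreenSim:
    """Simulate ``n_replicates`` arrays of a full screen with planted effects.

    ``effects`` is indexed by sample_id with (a subset of) columns
    ``ki67_scale, cparp_scale, apoptosis_frac, knockdown_frac, count_scale,
    transfection_frac``; every non-control sample on the layout must have a
    row (controls default to null effects).  Per-sample effects are shared
    across replicates; ``sample_effect_sd`` adds a per-sample latent log2
    Ki-67 effect shared between replicates (used to plant a target
    between-replicate concordance) and ``replicate_noise`` adds independent
    per-(sample, replicate) log2 noise.  Pin bias is drawn log-uniformly in
    ``pin_bias_range`` per (replicate, pin, channel).

    Raises ``ConfigurationError`` if a target sample lacks an effect entry.
    """
    if mode not in ("tables", "images"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    base = base_truth or SpotTruth()
    occupied = layout.occupied()
    target_ids = sorted({s.sample_id for s in occupied if s.sample_id != CONTROL_ID})
    missing = [t for t in target_ids if t not in effects.index]
    if missing:
        raise ConfigurationError(f"samples missing from effect table: {missing[:5]} ...")

    ss = np.random.SeedSequence(seed)
    latent_ss, pin_ss, spots_ss = ss.spawn(3)
    latent_rng = np.random.default_rng(latent_ss)
    pin_rng = np.random.default_rng(pin_ss)

    all_ids = target_ids + [CONTROL_ID]
    latent = (
        pd.Series(latent_rng.normal(0.0, sample_effect_sd, size=len(all_ids)), index=all_ids)
        if sample_effect_sd > 0
        else pd.Series(0.0, index=all_ids)
    )
    latent[CONTROL_ID] = 0.0

    n_pins = max(s.pin_id for s in layout.spots) + 1
    lo, hi = np.log(pin_bias_range[0]), np.log(pin_bias_range[1])
    pin_bias = np.exp(pin_rng.uniform(lo, hi, size=(n_replicates, n_pins, 4)))

    cell_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    spot_rows: list[dict] = []
    images: dict[tuple[int, int], FieldImage] = {}
    spot_rngs = np.random.default_rng(spots_ss)

    for rep in range(n_replicates):
        for spot in occupied:
            sid = spot.sample_id
            eff = effects.loc[sid] if sid in effects.index else None
            delta = float(latent[sid])
            if replicate_noise > 0:
                delta += float(spot_rngs.normal(0.0, replicate_noise))

            def _get(col: str, default: float) -> float:
                if eff is None or col not in eff.index or pd.isna(eff[col]):
                    return default
                return float(eff[col])

            bias = dict(zip(("dapi", "ki67", "cparp", "tugfp"), pin_bias[rep, spot.pin_id]))
            truth = replace(
                base,
                spot_id=spot.spot_id,
                sample_id=sid,
                pin_id=spot.pin_id,
                spot_diameter_um=spot.diameter_um,
                mean_cells=base.mean_cells * _get("count_scale", 1.0),
                knockdown_frac=_get("knockdown_frac", base.knockdown_frac),
                apoptosis_frac=_get("apoptosis_frac", base.apoptosis_frac),
                transfection_frac=_get("transfection_frac", base.transfection_frac),
                ki67_scale=_get("ki67_scale", 1.0) * 2.0**delta,
                cparp_scale=_get("cparp_scale", 1.0),
                pin_bias=bias,
            )
            cells = simulate_spot_cells(
                truth, spot_rngs, model=model, enforce_spacing=(mode == "images")
            )
            spot_rows.append(
                {
                    "replicate": rep,
                    "spot_id": spot.spot_id,
                    "sample_id": sid,
                    "pin_id": spot.pin_id,
                    "n_cells_true": len(cells),
                    "ki67_scale": truth.ki67_scale,
                    "cparp_scale": truth.cparp_scale,
                    "apoptosis_frac": truth.apoptosis_frac,
                    "knockdown_frac": truth.knockdown_frac,
                    "transfection_frac": truth.transfection_frac,
                }
            )
            ct = cells.copy()
            ct.insert(0, "replicate", rep)
            ct.insert(1, "spot_id", spot.spot_id)
            truth_frames.append(ct)
            if mode == "tables":
                rec = truth_to_records(
                    cells, truth, pixel_size_um, spot_center_um=(spot.x_um, spot.y_um)
                )
                rec.insert(0, "replicate", rep)
                cell_frames.append(rec)
            else:
                images[(rep, spot.spot_id)] = render_spot_image(
                    cells,
                    pixel_size_um=pixel_size_um,
                    noise_sd=noise_sd,
                    background=background,
                    seed=spot_rngs,
                    spot_diameter_um=spot.diameter_um,
                    pin_bias=bias,
                    spot_id=spot.spot_id,
                    spot_center_um=(spot.x_um, spot.y_um),
                )

    cells_df = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else pd.DataFrame()
    )
    return ScreenSim(
        cells=cells_df,
        spot_truth=pd.DataFrame(spot_rows),
        cell_truth=pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame(),
        images=images if mode == "images" else None,
    )


def latent_sd_for_correlation(target_r: float, measurement_sd: float) -> float:
    """Latent per-sample effect s.d. planting a between-replicate Pearson r.

    With independent per-replicate measurement noise of ``measurement_sd``
    (log2 index units) and a shared latent effect of s.d. ``s``, the expected
    replicate correlation is s^2 / (s^2 + measurement_sd^2); invert for s.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    return measurement_sd * math.sqrt(target_r / (1.0 - target_r))


def ki67_scale_for_index_shift(
    target_log2_shift: float,
    truth: SpotTruth | None = None,
    model: IntensityModel = DEFAULT_MODEL,
) -> float:
    """Ki-67 scale factor that shifts the expected spot index by a target.

    The spot index responds to ``ki67_scale`` sublinearly because apoptotic
    cells carry an unscaled Ki-67-negative floor: the expected cumulative
    Ki-67 per cell is ``(1-a) * kbar * s + a * k0`` (``a`` apoptosis
    fraction, ``kbar`` the cycling-population mean, ``k0`` the negative
    floor).  Solving for ``s`` makes the planted log2 index shift exact in
    expectation.
    """
    t = truth or SpotTruth()
    kbar = float(np.dot(t.cycle_probs, model.ki67_phase_means))
    a, k0 = t.apoptosis_frac, model.ki67_negative_mean
    base = (1.0 - a) * kbar + a * k0
    s = (base * 2.0**target_log2_shift - a * k0) / ((1.0 - a) * kbar)
    if s <= 0:
        raise ValueError(
            f"target shift {target_log2_shift} below the apoptotic Ki-67 floor"
        )
    return float(s)


def planted_shift_for_z(z_effect: float, n_samples: int, n_hits: int) -> float:
    """Raw index shift (in null-s.d. units) whose post-standardization hit
    z-score expectation equals ``z_effect``.

    Array-wide z-scoring is contaminated by the hits themselves (they move the
    mean and inflate the s.d.), so the raw planted shift must exceed the
    target z.  Solves  z = -d(1-f)/sqrt(1 + f d^2 (1-f))  for d, with
    f = n_hits/n_samples, and returns a signed shift matching ``z_effect``.
    """
    from scipy.optimize import brentq

    f = n_hits / n_samples
    target = abs(float(z_effect))

    def g(d: float) -> float:
        return d * (1 - f) / math.sqrt(1.0 + f * d * d * (1 - f)) - target

    hi = 10.0 * target + 10.0
    d = brentq(g, 0.0, hi)
    return -d if z_effect < 0 else d
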
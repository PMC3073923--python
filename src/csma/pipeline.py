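"""Run configuration and the layout -> simulate -> quantify -> score pipeline.

A single flat YAML config drives all stages; every stochastic stage receives
a child seed derived deterministically from the global seed and the stage
name, so a fixed (config, seed) pair reproduces every output byte for byte.
Stage boundaries log record counts (cells in, cells excluded, spots scored)
to keep filtering auditable; on stage failure, partial outputs are moved to a
``failed/`` directory and a non-zero status is returned.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .errors import ConfigurationError, PinNormalizationError
from .layout import (
    CONTROL_ID,
    ArrayLayout,
    SampleSheet,
    assign_samples,
    build_layout,
    read_gal,
    write_gal,
)
from .screenstats import (
    aggregate_spots,
    combine_and_call,
    pam_cluster,
    pin_normalize,
    rank_product,
    replicate_concordance,
    spot_index,
    zscore_array,
)
from .simgen import SpotTruth, null_effects, simulate_screen  # noqa: F401

log = logging.getLogger("csma")

_STAGES = ("layout", "simulate", "quantify", "score")


class LayoutConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_rows: int = Field(8, ge=1)
    n_cols: int = Field(12, ge=1)
    pitch_um: float = Field(500.0, gt=0)
    diameter_um: float = Field(200.0, gt=0)
    n_wells: int = Field(1, ge=1)
    n_pins: int = Field(4, ge=1)
    control_fraction: float = Field(0.05, ge=0, lt=1)


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_replicates: int = Field(2, ge=1)
    replicate_noise: float = Field(0.0, ge=0)
    sample_effect_sd: float = Field(0.0, ge=0)
    mode: Literal["tables", "images"] = "tables"
    mean_cells: float = Field(51.0, ge=0)
    sd_cells: float = Field(3.0, ge=0)
    apoptosis_frac: float = Field(0.05, ge=0, le=1)


class ImagingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pixel_size_um: float = Field(0.65, gt=0)
    ring_width_px: int = Field(15, ge=1)
    min_area_px: int = Field(25, ge=1)


class ScoringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float = Field(2.0, gt=0)  # |z| hit rule
    min_cells: int = Field(10, ge=1)
    rp_perms: int = Field(10000, ge=100)
    pam_k: int = Field(4, ge=1)


class RunConfig(BaseModel):
    """Validated configuration for one end-to-end run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "csma_run"
    n_genes: int = Field(24, ge=1)  # synthetic library size (2 constructs/gene)
    layout: LayoutConfig = LayoutConfig()
    simulate: SimulateConfig = SimulateConfig()
    imaging: ImagingConfig = ImagingConfig()
    scoring: ScoringConfig = ScoringConfig()
    log_level: str = "INFO"


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Validate a config mapping or YAML file; aggregate every violation.

    Unknown keys and out-of-range values are all collected into one
    :class:`ConfigurationError` report rather than failing at the first.
    """
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()
        ]
        raise ConfigurationError(
            "invalid configuration ({} problem{}):\n{}".format(
                e.error_count(), "s" if e.error_count() != 1 else "", "\n".join(lines)
            )
        ) from None


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across runs and platforms)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def score_arrays(
    cells: pd.DataFrame,
    threshold: float = 2.0,
    min_cells: int = 10,
    control_ids: tuple[str, ...] = (CONTROL_ID,),
    normalize_pins: bool | str = "auto",
) -> dict:
    """Score a quantified screen: per-array z, combined hits, concordance.

    ``cells`` must carry a ``replicate`` column plus the CellRecord columns.
    ``normalize_pins='auto'`` applies pin normalization when every pin has a
    usable control spot and skips it (with a warning) otherwise; ``True``
    enforces it and propagates the error.  Returns a dict with ``spots``
    (per replicate), ``z`` (samples x arrays), ``results`` (combined_z / hit
    per sample) and ``concordance_r`` (first two arrays, NaN with one array).
    """
    z_cols = {}
    ctrl_z_cols: dict[str, pd.Series] = {}
    spot_frames = []
    for rep, rep_cells in cells.groupby("replicate"):
        spots = aggregate_spots(rep_cells, min_cells=min_cells)
        if normalize_pins == "auto":
            try:
                spots = pin_normalize(spots, control_ids, min_cells=min_cells)
            except PinNormalizationError as e:
                log.warning("array %s: %s; scoring without pin normalization", rep, e)
        elif normalize_pins:
            spots = pin_normalize(spots, control_ids, min_cells=min_cells)
        spots = spot_index(spots, min_cells=min_cells)
        spots.insert(0, "replicate", rep)
        spot_frames.append(spots)
        scored = spots[~spots["sample_id"].isin(control_ids)]
        per_sample = scored.groupby("sample_id")["index"].mean()
        z_cols[f"array_{rep}"] = zscore_array(per_sample)
        # controls standardized against the sample distribution of the array
        mu, sd = float(per_sample.mean()), float(per_sample.std(ddof=0))
        ctrl = spots[spots["sample_id"].isin(control_ids)]
        ctrl_z_cols[f"array_{rep}"] = ((ctrl["index"] - mu) / sd).reset_index(drop=True)
    z = pd.DataFrame(z_cols)
    control_z = pd.DataFrame(ctrl_z_cols)
    results = combine_and_call(z, threshold=threshold)
    r = (
        replicate_concordance(z.iloc[:, 0], z.iloc[:, 1])
        if z.shape[1] >= 2
        else float("nan")
    )
    return {
        "spots": pd.concat(spot_frames, ignore_index=True),
        "z": z,
        "control_z": control_z,
        "results": results,
        "concordance_r": r,
    }


def estimate_null_index_sd(
    layout: ArrayLayout,
    n_pilots: int = 5,
    seed: int = 0,
    base_truth: SpotTruth | None = None,
    min_cells: int = 10,
) -> float:
    """Null spot-index s.d. (log2 units) averaged over pilot arrays.

    A single array's realized index s.d. fluctuates by ~10% with the pin-bias
    realization, so effect planting in s.d. units calibrates against the mean
    over several independent null pilot arrays.
    """
    ids = sorted({s.sample_id for s in layout.occupied() if s.sample_id != CONTROL_ID})
    eff = null_effects(ids)
    sds = []
    for i in range(n_pilots):
        child = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % 2**31)
        sim = simulate_screen(layout, eff, n_replicates=1, seed=child, base_truth=base_truth)
        spots = spot_index(
            pin_normalize(aggregate_spots(sim.cells, min_cells), min_cells=min_cells),
            min_cells=min_cells,
        )
        idx = spots[spots["sample_id"] != CONTROL_ID]["index"]
        sds.append(float(idx.std(ddof=0)))
    return float(np.mean(sds))


def run_pipeline(config: RunConfig, effects: pd.DataFrame | None = None) -> dict:
    """Execute layout -> simulate -> quantify -> score and write artifacts.

    Returns ``{"status": 0, "out_dir": ..., "results": DataFrame, ...}``.
    On stage failure partial outputs are quarantined under ``failed/`` and
    ``status`` is non-zero.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    t0 = time.time()
    stage = "layout"
    try:
        (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))

        lc = config.layout
        layout = build_layout(
            lc.n_rows, lc.n_cols, lc.pitch_um, lc.diameter_um, lc.n_wells, lc.n_pins
        )
        sheet = SampleSheet.from_gene_list([f"GENE{i:03d}" for i in range(config.n_genes)])
        layout = assign_samples(
            layout, sheet, lc.control_fraction, seed=stage_seed(config.seed, "layout")
        )
        write_gal(layout, out / "layout.gal")
        log.info("layout: %d spots, %d occupied", layout.n_spots, len(layout.occupied()))

        stage = "simulate"
        sc = config.simulate
        eff = effects if effects is not None else null_effects(
            sorted({s.sample_id for s in layout.occupied() if s.sample_id != CONTROL_ID})
        )
        sim = simulate_screen(
            layout,
            eff,
            n_replicates=sc.n_replicates,
            replicate_noise=sc.replicate_noise,
            sample_effect_sd=sc.sample_effect_sd,
            seed=stage_seed(config.seed, "simulate"),
            mode=sc.mode,
            base_truth=SpotTruth(
                mean_cells=sc.mean_cells,
                sd_cells=sc.sd_cells,
                apoptosis_frac=sc.apoptosis_frac,
                spot_diameter_um=lc.diameter_um,
            ),
            pixel_size_um=config.imaging.pixel_size_um,
        )
        log.info("simulate: %d replicates, %d cells", sc.n_replicates, len(sim.cells))

        stage = "quantify"
        if sc.mode == "images":
            from .imaging import assign_cells_to_spots, measure_cells, segment_nuclei

            frames = []
            for (rep, sid), img in sim.images.items():
                m = segment_nuclei(
                    img.channels["dapi"],
                    min_area_px=config.imaging.min_area_px,
                    pixel_size_um=config.imaging.pixel_size_um,
                )
                rec = measure_cells(m, img, ring_width_px=config.imaging.ring_width_px)
                rec.insert(0, "replicate", rep)
                frames.append(rec)
            cells = pd.concat(frames, ignore_index=True)
            cells = assign_cells_to_spots(cells, layout)
        else:
            cells = sim.cells
        n_excluded = int(cells["excluded"].sum()) if "excluded" in cells else 0
        cells.to_csv(out / "cells.csv", index=False)
        sim.spot_truth.to_csv(out / "spot_truth.csv", index=False)
        log.info("quantify: %d cells, %d excluded", len(cells), n_excluded)

        stage = "score"
        sconf = config.scoring
        scored = score_arrays(cells, threshold=sconf.threshold, min_cells=sconf.min_cells)
        results = scored["results"].copy()
        z = scored["z"]
        if z.shape[1] >= 2:
            rp = rank_product(z, n_perm=sconf.rp_perms, seed=stage_seed(config.seed, "score"))
            results = results.join(rp)
        if sconf.pam_k < len(z):
            pam = pam_cluster(z.fillna(0.0), k=sconf.pam_k)
            results["cluster"] = pam.labels
        results.insert(0, "sample_id", results.index)
        scored["spots"].to_csv(out / "spots.csv", index=False)
        results.to_csv(out / "screen_results.csv", index=False)
        meta = {
            "version": __version__,
            "seed": config.seed,
            "threshold": sconf.threshold,
            "concordance_r": scored["concordance_r"],
            "n_cells": int(len(cells)),
            "n_excluded": n_excluded,
            "n_spots_scored": int(scored["spots"]["index_defined"].sum()),
            "elapsed_s": round(time.time() - t0, 3),
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
        log.info("score: %d samples, r=%s", len(results), scored["concordance_r"])
        return {"status": 0, "out_dir": str(out), "results": results, **scored, "meta": meta}
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.iterdir():
            if f.is_file():
                shutil.move(str(f), failed / f.name)
        log.exception("stage %r failed; partial outputs quarantined in %s", stage, failed)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
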
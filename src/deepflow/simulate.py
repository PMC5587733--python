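"""Synthetic imaging-flow-cytometry-like single-cell images.

Each cell is driven by a continuous phase parameter ``t`` in [0, 1) that
is discretized into the seven canonical cell-cycle stages (G1, S, G2,
Prophase, Metaphase, Anaphase, Telophase) by cumulative stage priors.
Three channels are rendered per cell:

* **brightfield** — bright background, dark membrane ring and mid-gray
  interior; cell radius grows through interphase and the outline
  elongates through mitosis.
* **darkfield** — speckle (granularity) texture inside the cell whose
  density grows with ``t``.
* **fluorescence_dna** — a DNA-stain nucleus blob whose *integrated*
  intensity equals the cell's DNA content (1x genome in early G1, ramp
  to 2x through S, ~2x through mitosis).  Mitotic stages are rendered as
  a condensed band (Prophase/Metaphase), two separating lobes (Anaphase)
  and two separated lobes joined by a thin bridge (Telophase).

A small fraction of interphase cells is "damaged": broken membrane
(angular gaps in the ring), outgrowths on the boundary and a distorted
outline.  Damaged cells keep their ordinary interphase stage label, so
any structure a model finds for them is learned without supervision.

All morphology varies continuously with ``t``, which gives the data the
property classification-based process reconstruction relies on:
temporally adjacent stages look more alike than distant ones.

The renderer is deterministic: every cell draws from its own generator
spawned from the dataset seed, so images are reproducible and
independent of, e.g., the bleed-through setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import CellImageSet, save_dataset
from .errors import ConfigurationError, ParameterError

__all__ = [
    "STAGE_NAMES",
    "DEFAULT_STAGE_PRIORS",
    "INTERPHASE_PRIORS",
    "SyntheticConfig",
    "GroundTruth",
    "discretize_stage",
    "generate",
    "write_synthetic_dataset",
]

STAGE_NAMES = ["G1", "S", "G2", "Prophase", "Metaphase", "Anaphase", "Telophase"]

#: heavily interphase-weighted priors; interphase mass 0.978
DEFAULT_STAGE_PRIORS = (0.55, 0.25, 0.178, 0.010, 0.008, 0.002, 0.002)

#: interphase-only task (three classes from continuous t)
INTERPHASE_PRIORS = (0.45, 0.30, 0.25, 0.0, 0.0, 0.0, 0.0)

CHANNEL_NAMES = ["brightfield", "darkfield", "fluorescence_dna"]

#: total fluorescence energy (pixel-sum) of a 1x-genome nucleus
_DNA_ENERGY = 100.0


@dataclass
class SyntheticConfig:
    n_cells: int
    side: int = 64
    stage_priors: tuple = DEFAULT_STAGE_PRIORS
    damaged_fraction: float = 0.02
    noise_sd: float = 0.02
    bleed_through: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.stage_priors, dtype=float)
        if len(p) != 7 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "stage_priors must be 7 nonnegative fractions summing to 1"
            )
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if not (0 <= self.damaged_fraction < 1):
            raise ConfigurationError("damaged_fraction must be in [0, 1)")
        if not (0 <= self.bleed_through < 1):
            raise ConfigurationError("bleed_through must be in [0, 1)")


@dataclass
class GroundTruth:
    """Hidden per-cell state behind a synthetic image set."""

    t: np.ndarray  # (n,) continuous phase parameter in [0, 1)
    stage: np.ndarray  # (n,) index into STAGE_NAMES
    damaged: np.ndarray  # (n,) bool
    dna_content: np.ndarray  # (n,) positive reals
    stage_names: list[str] = field(default_factory=lambda: list(STAGE_NAMES))


def discretize_stage(t, priors=DEFAULT_STAGE_PRIORS) -> np.ndarray | int:
    """Map phase parameter(s) in [0, 1) to stage indices.

    Stage boundaries are the cumulative priors; intervals are half-open
    [lo, hi), so zero-prior stages are never produced.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ParameterError("t must lie in [0, 1)")
    cum = np.cumsum(np.asarray(priors, dtype=float))
    idx = np.searchsorted(cum, arr, side="right")
    idx = np.minimum(idx, 6)  # guard against cum[-1] rounding below 1
    return int(idx) if np.isscalar(t) else idx


def _dna_of_t(t: np.ndarray, priors) -> np.ndarray:
    """Strictly increasing DNA content over interphase, ~2x through mitosis.

    1x at the start of G1, a small accumulation slope within G1 and G2
    around the canonical 1x -> 2x S-phase ramp, 2x in mitosis.
    """
    p = np.asarray(priors, dtype=float)
    p_inter = p[:3].sum()
    dna = np.full_like(t, 2.0)
    inter = t < p_inter
    u = t[inter] / p_inter
    g1_end = p[0] / p_inter
    s_end = (p[0] + p[1]) / p_inter
    d = np.empty_like(u)
    in_g1 = u < g1_end
    in_s = (u >= g1_end) & (u < s_end)
    in_g2 = u >= s_end
    d[in_g1] = 1.0 + 0.08 * (u[in_g1] / max(g1_end, 1e-9))
    d[in_s] = 1.08 + 0.84 * ((u[in_s] - g1_end) / max(s_end - g1_end, 1e-9))
    d[in_g2] = 1.92 + 0.08 * ((u[in_g2] - s_end) / max(1.0 - s_end, 1e-9))
    dna[inter] = d
    return dna


def _gauss2d(xx, yy, cx, cy, sx, sy, theta=0.0):
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    return np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def _render_cell(t: float, stage: int, damaged: bool, dna: float,
                 side: int, rng: np.random.Generator):
    """Render the three clean (noise-free) channels for one cell."""
    ax = np.linspace(-1.0, 1.0, side)
    xx, yy = np.meshgrid(ax, ax)
    cx, cy = rng.uniform(-0.05, 0.05, size=2)
    theta = rng.uniform(0.0, np.pi)  # cell orientation

    p_inter = 0.978  # morphology scale uses a fixed interphase span
    if stage < 3:
        u = min(t / p_inter, 1.0)
        m = 0.0
    else:
        u = 1.0
        m = min(max((t - p_inter) / (1.0 - p_inter), 0.0), 1.0)

    r = 0.38 + 0.22 * u  # cell radius in half-side units
    ecc = 0.25 * m  # mitotic elongation
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    d = np.sqrt((xr / (1.0 + ecc)) ** 2 + (yr / (1.0 - 0.5 * ecc)) ** 2)

    if damaged:
        ang = np.arctan2(yr, xr)
        phase = rng.uniform(0, 2 * np.pi)
        d = d * (1.0 + 0.25 * np.sin(4 * ang + phase) + 0.10 * np.sin(7 * ang - phase))

    # --- brightfield ---------------------------------------------------
    interior = 1.0 / (1.0 + np.exp(-(r - 0.05 - d) / 0.02))
    ring = np.exp(-(((d - r) / 0.05) ** 2))
    if damaged:
        ang = np.arctan2(yr, xr)
        gap_mask = np.ones_like(ring)
        for _ in range(rng.integers(3, 6)):
            a0 = rng.uniform(-np.pi, np.pi)
            width = rng.uniform(0.5, 0.9)
            delta = np.angle(np.exp(1j * (ang - a0)))
            gap_mask *= 1.0 - np.exp(-((delta / width) ** 2))
        ring = ring * gap_mask
    bf = 0.80 - 0.25 * interior - 0.55 * ring
    if damaged:  # dark outgrowth blobs spilling past the broken boundary
        for _ in range(rng.integers(3, 7)):
            a0 = rng.uniform(-np.pi, np.pi)
            rr = r + rng.uniform(0.06, 0.18)
            ox = cx + rr * np.cos(a0)
            oy = cy + rr * np.sin(a0)
            bf -= 0.55 * _gauss2d(xx, yy, ox, oy, 0.10, 0.10)
        # leaked cytoplasm: bright mottling inside the cell
        for _ in range(3):
            a0 = rng.uniform(-np.pi, np.pi)
            px = cx + rng.uniform(0.0, 0.5) * r * np.cos(a0)
            py = cy + rng.uniform(0.0, 0.5) * r * np.sin(a0)
            bf += 0.25 * _gauss2d(xx, yy, px, py, 0.12, 0.12)
    bf = np.clip(bf, 0.02, 0.85)

    # --- darkfield -----------------------------------------------------
    inside = d < r
    density = 0.03 + 0.12 * min(t, 1.0)
    dots = (rng.random((side, side)) < density) & inside
    df = gaussian_filter(dots.astype(np.float64), sigma=0.7) * 2.2
    df += 0.03
    if damaged:  # bright disordered patches where granules clump
        for _ in range(rng.integers(2, 4)):
            a0 = rng.uniform(-np.pi, np.pi)
            px = cx + rng.uniform(0.2, 0.8) * r * np.cos(a0)
            py = cy + rng.uniform(0.2, 0.8) * r * np.sin(a0)
            df += 0.6 * _gauss2d(xx, yy, px, py, 0.20, 0.20)
    df = np.clip(df, 0.0, 0.85)

    # --- fluorescence (DNA) --------------------------------------------
    if stage <= 3:  # interphase + prophase: single nucleus, condensing
        sn = (0.45 - 0.12 * m) * r if stage == 3 else 0.45 * r
        blob = _gauss2d(xx, yy, cx, cy, sn, sn)
    elif stage == 4:  # metaphase: condensed band across the middle
        blob = _gauss2d(xx, yy, cx, cy, 0.55 * r, 0.13 * r, theta + np.pi / 2)
    else:
        sep = (0.45 if stage == 5 else 0.80) * r
        lx, ly = sep * np.cos(theta), sep * np.sin(theta)
        blob = _gauss2d(xx, yy, cx - lx, cy - ly, 0.20 * r, 0.20 * r) \
            + _gauss2d(xx, yy, cx + lx, cy + ly, 0.20 * r, 0.20 * r)
        if stage == 6:  # telophase: thin chromatin bridge between lobes
            blob += 0.25 * _gauss2d(xx, yy, cx, cy, sep, 0.05 * r, theta)
    total = blob.sum()
    energy = dna * _DNA_ENERGY * (side / 64.0) ** 2
    fl = blob * (energy / total) if total > 0 else blob
    fl += 0.01
    return bf, df, fl


def generate(config: SyntheticConfig) -> tuple[CellImageSet, GroundTruth]:
    """Draw ``n_cells`` synthetic cells; deterministic under the seed.

    Returns the image set (channels brightfield, darkfield,
    fluorescence_dna; ``dna_content`` covariate; stage labels restricted
    to stages with nonzero prior) and the hidden ground truth.
    """
    priors = np.asarray(config.stage_priors, dtype=float)
    root = np.random.default_rng(config.seed)
    t = root.uniform(0.0, 1.0, size=config.n_cells)
    t = np.clip(t, 0.0, np.nextafter(1.0, 0.0))
    stage = discretize_stage(t, priors)
    dna = _dna_of_t(t, priors)

    p_inter = priors[:3].sum()
    interphase = stage < 3
    damaged = np.zeros(config.n_cells, dtype=bool)
    if config.damaged_fraction > 0 and p_inter > 0:
        p_dam = min(config.damaged_fraction / p_inter, 1.0)
        damaged = interphase & (root.uniform(size=config.n_cells) < p_dam)

    present = [i for i in range(7) if priors[i] > 0]
    label_names = [STAGE_NAMES[i] for i in present]
    remap = {s: k for k, s in enumerate(present)}
    labels = np.array([remap[int(s)] for s in stage], dtype=np.intp)

    streams = np.random.SeedSequence([config.seed, 7]).spawn(config.n_cells)
    images = np.empty((config.n_cells, 3, config.side, config.side), dtype=np.float32)
    beta = config.bleed_through
    for i in range(config.n_cells):
        rng = np.random.default_rng(streams[i])
        bf, df, fl = _render_cell(
            float(t[i]), int(stage[i]), bool(damaged[i]), float(dna[i]),
            config.side, rng,
        )
        if config.noise_sd > 0:
            bf = bf + rng.normal(0.0, config.noise_sd, bf.shape)
            df = df + rng.normal(0.0, config.noise_sd, df.shape)
            fl = fl + rng.normal(0.0, config.noise_sd, fl.shape)
        bf = np.clip(bf, 0.0, 1.0).astype(np.float32)
        df = np.clip(df, 0.0, 1.0).astype(np.float32)
        fl = np.clip(fl, 0.0, 1.0).astype(np.float32)
        if beta > 0:
            # mixed at storage precision so bf(beta) == bf(0) + beta*fl exactly
            bf = np.clip(bf + np.float32(beta) * fl, 0.0, 1.0).astype(np.float32)
        images[i, 0], images[i, 1], images[i, 2] = bf, df, fl

    dataset = CellImageSet(
        cell_ids=[f"cell{i:06d}" for i in range(config.n_cells)],
        images=images,
        channel_names=list(CHANNEL_NAMES),
        labels=labels,
        label_names=label_names,
        covariates={"dna_content": dna.copy()},
    )
    dataset.validate()
    truth = GroundTruth(t=t, stage=stage, damaged=damaged, dna_content=dna.copy())
    return dataset, truth


def write_synthetic_dataset(config: SyntheticConfig, out_dir: str,
                            fmt: str = "png") -> str:
    """Generate and write a dataset to disk; returns the manifest path.

    Alongside the images and ``manifest.csv`` (which carries the
    ``dna_content`` covariate), a ``truth.csv`` with the hidden ``t`` and
    ``damaged`` flags and a ``config.yaml`` are written.
    """
    import os

    import pandas as pd
    import yaml

    dataset, truth = generate(config)
    manifest = save_dataset(dataset, out_dir, fmt=fmt)
    pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "t": truth.t,
            "stage": [STAGE_NAMES[s] for s in truth.stage],
            "damaged": truth.damaged.astype(int),
        }
    ).to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    cfg = {
        "n_cells": config.n_cells,
        "side": config.side,
        "stage_priors": [float(p) for p in config.stage_priors],
        "damaged_fraction": config.damaged_fraction,
        "noise_sd": config.noise_sd,
        "bleed_through": config.bleed_through,
        "seed": config.seed,
    }
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)
    return manifest
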
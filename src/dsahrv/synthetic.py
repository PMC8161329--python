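"""Synthetic RR-segment generator for the two rhythm classes.

Sinus-rhythm (SR) segments are near-constant: a baseline interval with a
slow sinusoidal modulation (respiratory-like variability) plus small
Gaussian jitter, so they symbolize to long runs of the middle symbol.
PAF-like segments are serially uncorrelated draws — uniform by default,
optionally gamma — with a variance far exceeding the modulation band,
so their symbol sequences are high-entropy.  This reproduces the
qualitative contrast the pipeline exploits (regular rhythms concentrate
transition mass in one cell; fibrillation spreads it) without modelling
real AF electrophysiology.

Generation is deterministic: each segment's random stream is derived
from the config seed and the segment id, so the same call always yields
the same series and datasets are reproducible byte-for-byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .rr_io import RRSeries, write_rr_csv

__all__ = ["SynthConfig", "gen_sr_segment", "gen_paf_segment", "gen_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings (times in seconds).

    SR defaults give a ~70 bpm rhythm with ±0.03 s modulation and 0.01 s
    jitter — comfortably inside the middle symbol bin for t=0.05.  The
    PAF uniform range (0.40–1.20 s) spans all bins of any vocabulary.
    """

    n_per_class: int = 60
    duration_s: float = 60.0
    sr_mean: float = 0.85
    sr_jitter_sd: float = 0.01
    sr_mod_amp: float = 0.03
    sr_mod_freq: float = 0.1  # cycles per beat
    paf_low: float = 0.40
    paf_high: float = 1.20
    paf_distribution: str = "uniform"  # or "gamma" (same mean/variance)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sr_mean <= 0:
            raise ValueError("invalid synthesis config: durations and means must be > 0")
        if self.sr_jitter_sd < 0 or self.sr_mod_amp < 0:
            raise ValueError("invalid synthesis config: noise amplitudes must be >= 0")
        if not 0 < self.paf_low < self.paf_high:
            raise ValueError("invalid synthesis config: need 0 < paf_low < paf_high")
        if self.paf_distribution not in ("uniform", "gamma"):
            raise ValueError("invalid synthesis config: unknown paf_distribution")


RR_FLOOR = 0.2  # physiological floor, seconds


def _rng(cfg: SynthConfig, segment_id: str) -> np.random.Generator:
    # segment stream keyed on (seed, id) so each segment is independently reproducible
    return np.random.default_rng([cfg.seed, zlib.crc32(segment_id.encode())])


def _fill_duration(draw, duration_s: float) -> np.ndarray:
    """Append beats until cumulative time reaches the target duration."""
    rr: list[float] = []
    elapsed = 0.0
    j = 0
    while elapsed < duration_s:
        r = draw(j)
        rr.append(r)
        elapsed += r
        j += 1
    return np.array(rr)


def gen_sr_segment(cfg: SynthConfig, segment_id: str) -> RRSeries:
    """Generate one sinus-rhythm-like segment."""
    rng = _rng(cfg, segment_id)

    def draw(j: int) -> float:
        r = (
            cfg.sr_mean
            + cfg.sr_mod_amp * np.sin(2 * np.pi * cfg.sr_mod_freq * j)
            + rng.normal(0.0, cfg.sr_jitter_sd)
        )
        return max(r, RR_FLOOR)

    return RRSeries(segment_id, _fill_duration(draw, cfg.duration_s), label="SR")


def gen_paf_segment(cfg: SynthConfig, segment_id: str) -> RRSeries:
    """Generate one PAF-like segment of serially uncorrelated intervals."""
    rng = _rng(cfg, segment_id)
    if cfg.paf_distribution == "uniform":
        def draw(j: int) -> float:
            return float(rng.uniform(cfg.paf_low, cfg.paf_high))
    else:  # gamma with the uniform's mean and variance
        mean = (cfg.paf_low + cfg.paf_high) / 2
        var = (cfg.paf_high - cfg.paf_low) ** 2 / 12
        shape, scale = mean**2 / var, var / mean
        def draw(j: int) -> float:
            return max(float(rng.gamma(shape, scale)), RR_FLOOR)

    return RRSeries(segment_id, _fill_duration(draw, cfg.duration_s), label="PAF")


def gen_dataset(
    cfg: SynthConfig, outdir: str | Path | None = None
) -> tuple[list[RRSeries], dict[str, str]]:
    """Generate a balanced labeled dataset of 2·n_per_class segments.

    Returns the segments and a ``segment_id → label`` manifest; when
    ``outdir`` is given, also writes ``rr.csv`` and ``manifest.csv``.
    """
    if cfg.n_per_class < 1:
        raise ValueError("empty dataset request: n_per_class must be >= 1")
    width = len(str(cfg.n_per_class - 1))
    segments = [
        gen_sr_segment(cfg, f"sr_{i:0{width}d}") for i in range(cfg.n_per_class)
    ] + [
        gen_paf_segment(cfg, f"paf_{i:0{width}d}") for i in range(cfg.n_per_class)
    ]
    manifest = {s.segment_id: s.label for s in segments}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_rr_csv(segments, outdir / "rr.csv")
        import pandas as pd

        pd.DataFrame(
            {"segment_id": list(manifest), "label": list(manifest.values())}
        ).to_csv(outdir / "manifest.csv", index=False)
    return segments, manifest


def with_seed(cfg: SynthConfig, seed: int) -> SynthConfig:
    """A copy of the config with a different seed."""
    return replace(cfg, seed=seed)
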
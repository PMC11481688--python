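"""Ground-truth-labelled synthetic data for both pipeline branches.

Imaging: vesicles are membrane-like annuli — marker molecules sit on a circle
of the particle's lognormal-drawn radius, so the radius-of-gyration feature
recovers the true radius — while antibody aggregates are tight Gaussian
clouds carrying a single channel only (the antibody-control design).  Each
molecule blinks a geometric number of times; consecutive blinks are separated
by at most ``frame_gap + 1`` frames so temporal grouping can re-assemble
them; every blink gets isotropic localization noise (default 10 nm SD,
typical dSTORM precision).  Free-dye background localizations are uniform.

Flow: Poisson particle arrivals; each particle adds a Gaussian SSC pulse and,
depending on its phenotype, fluorescence pulses, on top of white noise.

Identical seed and config give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from evpipe.flow_events import FLOW_PHENOTYPES, FlowTrace
from evpipe.localization_io import (
    AcquisitionMetadata,
    Channel,
    LOC_COLUMNS,
    LocalizationTable,
)

GROUND_TRUTH_COLUMNS = [
    "particle_id",
    "kind",
    "x",
    "y",
    "radius_nm",
    "phenotype",
    "n_mol_ch1",
    "n_mol_ch2",
]


@dataclass
class ImagingSimConfig:
    n_ev: int = 500
    n_aggregate: int = 0
    ev_radius_median: float = 60.0
    ev_radius_sigma: float = 0.4
    ab_radius_median: float = 20.0
    ab_radius_sigma: float = 0.4
    dp_fraction: float = 0.59
    # single-positive particles must clear the >15-molecule cluster gate on
    # one marker alone, so the default copy number sits well above it
    molecules_per_marker: float = 20.0
    localizations_per_molecule: float = 5.0
    background_locs_per_um2: float = 0.0
    # sparse default density: keeps the chance of two particles falling
    # within one linking radius (which would merge them) below ~2%
    fov_size_um: float = 100.0
    loc_precision_nm: float = 10.0
    frames_per_channel: int = 1500
    frame_gap: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dp_fraction <= 1.0:
            raise ValueError("dp_fraction must be in [0, 1]")
        for name in ("ev_radius_median", "ab_radius_median", "fov_size_um",
                     "molecules_per_marker", "localizations_per_molecule"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FlowSimConfig:
    event_rate_per_min: float = 12000.0
    duration_ms: float = 5000.0
    dt_ms: float = 0.005
    noise_sd: float = 1.0
    pulse_width_ms: float = 0.02
    phenotype_mix: tuple[float, float, float, float] = (0.85, 0.05, 0.05, 0.05)
    ssc_scale: float = 40.0
    fl_scale: tuple[float, float] = (30.0, 30.0)
    amplitude_sigma: float = 0.3  # lognormal jitter on pulse heights
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.phenotype_mix) - 1.0) > 1e-9:
            raise ValueError("phenotype_mix must sum to 1")
        if self.event_rate_per_min <= 0 or self.duration_ms <= 0:
            raise ValueError("rate and duration must be > 0")


def _blink_frames(
    rng: np.random.Generator, n_locs: int, frames: int, frame_gap: int
) -> np.ndarray:
    """Frame indices for one molecule's blinks, chained within the frame gap."""
    steps = rng.integers(1, frame_gap + 2, size=n_locs - 1) if n_locs > 1 else np.empty(0, int)
    span = int(steps.sum())
    start = int(rng.integers(0, max(1, frames - span)))
    return start + np.concatenate([[0], np.cumsum(steps)]).astype(np.int64)


def simulate_imaging(
    cfg: ImagingSimConfig, seed: int | None = None
) -> tuple[LocalizationTable, pd.DataFrame]:
    """Simulate a two-channel localization table plus its ground truth.

    Returns ``(table, truth)``; ``truth`` has one row per particle
    (``GROUND_TRUTH_COLUMNS``) and is sufficient to score clustering recall,
    phenotype accuracy and correction quality without re-simulation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fov_nm = cfg.fov_size_um * 1000.0

    truth_rows = []
    loc_rows = []  # (frame, x, y, channel)

    def emit_molecules(mol_xy: np.ndarray, channel: int) -> None:
        for mx, my in mol_xy:
            n_locs = int(rng.geometric(1.0 / cfg.localizations_per_molecule))
            frames = _blink_frames(rng, n_locs, cfg.frames_per_channel, cfg.frame_gap)
            noise = rng.normal(0.0, cfg.loc_precision_nm, size=(n_locs, 2))
            for f, (dx, dy) in zip(frames, noise):
                loc_rows.append((int(f), mx + dx, my + dy, channel))

    n_total = cfg.n_ev + cfg.n_aggregate
    centres = rng.uniform(0.0, fov_nm, size=(n_total, 2))

    # vesicles: annular marker placement, phenotype by configured mix
    ev_radii = rng.lognormal(np.log(cfg.ev_radius_median), cfg.ev_radius_sigma, cfg.n_ev)
    u = rng.uniform(size=cfg.n_ev)
    single_split = rng.uniform(size=cfg.n_ev) < 0.5
    for i in range(cfg.n_ev):
        cx, cy = centres[i]
        if u[i] < cfg.dp_fraction:
            pheno, has_ch1, has_ch2 = "double_positive", True, True
        elif single_split[i]:
            pheno, has_ch1, has_ch2 = "CD81_only", True, False
        else:
            pheno, has_ch1, has_ch2 = "CD9_only", False, True
        n_mol = {1: 0, 2: 0}
        for ch, has in ((int(Channel.CH1), has_ch1), (int(Channel.CH2), has_ch2)):
            if not has:
                continue
            k = int(rng.poisson(cfg.molecules_per_marker))
            n_mol[ch] = k
            if k:
                theta = rng.uniform(0, 2 * np.pi, k)
                mol_xy = np.column_stack(
                    [cx + ev_radii[i] * np.cos(theta), cy + ev_radii[i] * np.sin(theta)]
                )
                emit_molecules(mol_xy, ch)
        truth_rows.append(
            (i, "ev", cx, cy, float(ev_radii[i]), pheno, n_mol[1], n_mol[2])
        )

    # aggregates: one-channel Gaussian clouds with Rg matching the drawn radius
    ab_radii = rng.lognormal(np.log(cfg.ab_radius_median), cfg.ab_radius_sigma, cfg.n_aggregate)
    ab_channels = rng.integers(1, 3, size=cfg.n_aggregate)
    for j in range(cfg.n_aggregate):
        pid = cfg.n_ev + j
        cx, cy = centres[pid]
        ch = int(ab_channels[j])
        k = int(rng.poisson(cfg.molecules_per_marker))
        if k:
            mol_xy = rng.normal(
                loc=(cx, cy), scale=ab_radii[j] / np.sqrt(2.0), size=(k, 2)
            )
            emit_molecules(mol_xy, ch)
        pheno = "CD81_only" if ch == int(Channel.CH1) else "CD9_only"
        truth_rows.append(
            (pid, "aggregate", cx, cy, float(ab_radii[j]), pheno,
             k if ch == 1 else 0, k if ch == 2 else 0)
        )

    # free-dye background: single-blink localizations, uniform in space/frames
    if cfg.background_locs_per_um2 > 0:
        n_bg = int(rng.poisson(cfg.background_locs_per_um2 * cfg.fov_size_um**2))
        bg_xy = rng.uniform(0.0, fov_nm, size=(n_bg, 2))
        bg_frames = rng.integers(0, cfg.frames_per_channel, size=n_bg)
        bg_ch = rng.integers(1, 3, size=n_bg)
        for (bx, by), f, ch in zip(bg_xy, bg_frames, bg_ch):
            loc_rows.append((int(f), bx, by, int(ch)))

    if n_total > 1:
        tree = cKDTree(centres)
        dists, _ = tree.query(centres, k=2)
        overlap = float((dists[:, 1] < 300.0).mean())
        if overlap > 0.05:
            warnings.warn(
                f"{overlap:.0%} of particle footprints overlap; density too high",
                RuntimeWarning,
            )

    df = pd.DataFrame(loc_rows, columns=["frame", "x", "y", "channel"])
    df["photons"] = np.nan
    df.insert(0, "id", np.arange(len(df), dtype=np.int64))
    if len(df):
        df["frame"] = df["frame"].astype(np.int64)
        df["channel"] = df["channel"].astype(np.int64)
        df[["x", "y"]] = df[["x", "y"]].clip(0.0, fov_nm)
    table = LocalizationTable(
        df=df[LOC_COLUMNS],
        metadata=AcquisitionMetadata(
            frames_per_channel=cfg.frames_per_channel, fov_extent_nm=fov_nm
        ),
    )
    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return table, truth


def simulate_flow(
    cfg: FlowSimConfig, seed: int | None = None
) -> tuple["FlowTrace", pd.DataFrame]:
    """Simulate a three-channel flow trace plus per-arrival ground truth.

    Returns ``(trace, truth)`` where ``truth`` lists arrival time, phenotype
    and the pulse amplitudes of every particle.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_samples = int(round(cfg.duration_ms / cfg.dt_ms))
    t = np.arange(n_samples) * cfg.dt_ms
    ssc = rng.normal(0.0, cfg.noise_sd, n_samples)
    fl1 = rng.normal(0.0, cfg.noise_sd, n_samples)
    fl2 = rng.normal(0.0, cfg.noise_sd, n_samples)

    rate_per_ms = cfg.event_rate_per_min / 60000.0
    margin = 4 * cfg.pulse_width_ms
    n_events = int(rng.poisson(rate_per_ms * cfg.duration_ms))
    times = np.sort(rng.uniform(margin, cfg.duration_ms - margin, n_events))
    phenos = rng.choice(len(FLOW_PHENOTYPES), size=n_events, p=cfg.phenotype_mix)

    if n_events > 1:
        gaps = np.diff(times)
        frac_overlap = float((gaps < 6 * cfg.pulse_width_ms).mean())
        if frac_overlap > 0.10:
            warnings.warn(
                f"{frac_overlap:.0%} of pulses overlap; lower the event rate",
                RuntimeWarning,
            )

    w = cfg.pulse_width_ms
    half = int(np.ceil(4 * w / cfg.dt_ms))
    truth_rows = []
    for time, ph_idx in zip(times, phenos):
        pheno = FLOW_PHENOTYPES[ph_idx]
        centre = int(round(time / cfg.dt_ms))
        sl = slice(max(0, centre - half), min(n_samples, centre + half + 1))
        idx = np.arange(sl.start, sl.stop)
        shape = np.exp(-0.5 * (((idx * cfg.dt_ms) - time) / w) ** 2)
        a_ssc = cfg.ssc_scale * rng.lognormal(0.0, cfg.amplitude_sigma)
        ssc[sl] += a_ssc * shape
        a1 = a2 = 0.0
        if pheno in ("CD9_only", "double_positive"):
            a1 = cfg.fl_scale[0] * rng.lognormal(0.0, cfg.amplitude_sigma)
            fl1[sl] += a1 * shape
        if pheno in ("CD81_only", "double_positive"):
            a2 = cfg.fl_scale[1] * rng.lognormal(0.0, cfg.amplitude_sigma)
            fl2[sl] += a2 * shape
        truth_rows.append((float(time), pheno, a_ssc, a1, a2))

    trace = FlowTrace(time_ms=t, ssc=ssc, fl1=fl1, fl2=fl2)
    truth = pd.DataFrame(
        truth_rows, columns=["time_ms", "phenotype", "ssc_amp", "fl1_amp", "fl2_amp"]
    )
    return trace, truth
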
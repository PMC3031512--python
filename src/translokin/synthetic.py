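"""Synthetic translocation datasets with ground truth.

No public dataset of per-cell reporter traces exists for this experimental
design, so every pipeline stage is exercised against generated data whose
statistical structure mirrors the live-imaging study design: 3 explants of
10 tracked cells each, sampled every 10 minutes over 60–120 minutes, a
baseline nuclear-to-cytoplasm ratio near 1, a saturating first-order rise
under stimulation, cell-to-cell variability, additive measurement noise and
a small fraction of cells whose reporter is constitutively nuclear
("spontaneous translocators") regardless of stimulation.

Per-cell heterogeneity is log-normal in the time constant, the steady-state
response amplitude and the baseline ratio — the minimal positive-support
choice, since only SD error bars (not a distribution) are available for real
data. Measurement noise is additive Gaussian on the ratio R at the trace
level; pixel-level Poisson-Gaussian noise exists only in the image renderer.
Spontaneous cells carry an elevated nuclear ratio from t = 0 (not stimulus
leakage), so after normalization to their own pre-stimulus ratio they
contribute flat traces.

With all variability and noise switched off the generator reduces exactly to
the first-order model: it contains no structure the model cannot represent.
Ground truth is persisted alongside the data and is never read by any
fitting code path.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

import tifffile

from .errors import InvalidArgumentError, LayoutOverflowError, ParseError
from .model import TranslocationModel, simulate
from .quantify import CellTrace, read_traces_csv, write_traces_csv
from .stimulus import RegionSchedule

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "ImageLayout",
    "generate_traces",
    "render_frames",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters of the trace generator.

    Defaults mirror the live-imaging design: 3 explants x 10 cells,
    10-minute sampling over 120 minutes, stimulus amplitude 25 µM carried by
    the schedule, population-mean time constant 16.6 min, population-mean
    steady-state differential 1.0 under continuous stimulation, baseline
    ratio 1.0, 20% cell-to-cell coefficient of variation, 5% measurement
    noise and a 5% spontaneous-translocator fraction.
    """

    n_explants: int = 3
    cells_per_explant: int = 10
    region_assignment: tuple[str, ...] | None = None
    tau_mean: float = 16.6  # min
    tau_cv: float = 0.2
    gain_mean: float = 1.0  # steady-state y under CS (= K*C0)
    gain_cv: float = 0.2
    baseline_mean: float = 1.0  # pre-stimulus nuclear/cytoplasm ratio
    baseline_cv: float = 0.05
    noise_sigma: float = 0.05  # additive Gaussian on R, fraction of steady state
    spontaneous_fraction: float = 0.05
    sample_interval: float = 10.0  # min
    duration: float = 120.0  # min
    cyt_intensity: float = 100.0  # arbitrary units, emitted I_cyt level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_explants < 1 or self.cells_per_explant < 1:
            raise InvalidArgumentError("need at least one explant and cell")
        for cv in (self.tau_cv, self.gain_cv, self.baseline_cv):
            if cv < 0:
                raise InvalidArgumentError("CVs must be nonnegative")
        if not 0.0 <= self.spontaneous_fraction <= 1.0:
            raise InvalidArgumentError("spontaneous_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise InvalidArgumentError("noise_sigma must be nonnegative")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise InvalidArgumentError("sampling parameters must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_explants * self.cells_per_explant

    @property
    def sample_times(self) -> np.ndarray:
        n = int(round(self.duration / self.sample_interval))
        return np.linspace(0.0, n * self.sample_interval, n + 1)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["region_assignment"] = (
            list(self.region_assignment) if self.region_assignment else None
        )
        return d

    @classmethod
    def from_json_dict(cls, obj: dict) -> "GeneratorConfig":
        obj = dict(obj)
        if obj.get("region_assignment"):
            obj["region_assignment"] = tuple(obj["region_assignment"])
        return cls(**obj)


@dataclass(frozen=True)
class GroundTruth:
    """Per-cell generating parameters, persisted for recovery testing only."""

    cell_ids: tuple[str, ...]
    tau: tuple[float, ...]
    gain: tuple[float, ...]
    baseline: tuple[float, ...]
    spontaneous: tuple[bool, ...]
    region: tuple[str, ...]
    config: GeneratorConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_ids": list(self.cell_ids),
                "tau": list(self.tau),
                "gain": list(self.gain),
                "baseline": list(self.baseline),
                "spontaneous": list(self.spontaneous),
                "region": list(self.region),
                "config": self.config.to_json_dict(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            cell_ids=tuple(obj["cell_ids"]),
            tau=tuple(obj["tau"]),
            gain=tuple(obj["gain"]),
            baseline=tuple(obj["baseline"]),
            spontaneous=tuple(obj["spontaneous"]),
            region=tuple(obj["region"]),
            config=GeneratorConfig.from_json_dict(obj["config"]),
        )


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Log-normal draws parameterized by arithmetic mean and CV; CV=0 is exact."""
    if cv == 0.0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def generate_traces(
    config: GeneratorConfig, schedule: RegionSchedule
) -> tuple[list[CellTrace], GroundTruth]:
    """Draw a cohort of per-cell traces under a region schedule.

    Each cell receives (tau_i, gain_i, baseline_i) from log-normal
    populations and follows the exact first-order response to its region's
    profile; spontaneous cells sit at an elevated nuclear ratio from t = 0
    independent of the stimulus. The emitted ratio is
    R(t) = baseline_i * (1 + y_i(t)) + noise, with the noise SD expressed as
    ``noise_sigma`` times the population-mean steady-state response. I_cyt is
    held at ``cyt_intensity`` and I_nuc = R * I_cyt.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.region_assignment
    if labels is None:
        cycle = schedule.regions
        labels = tuple(cycle[i % len(cycle)] for i in range(config.n_cells))
    if len(labels) != config.n_cells:
        raise InvalidArgumentError(
            f"{len(labels)} region labels for {config.n_cells} cells"
        )
    for lab in labels:
        if lab not in schedule.regions:
            raise InvalidArgumentError(f"region label {lab!r} not in schedule")

    n = config.n_cells
    taus = _lognormal(rng, config.tau_mean, config.tau_cv, n)
    gains = _lognormal(rng, config.gain_mean, config.gain_cv, n)
    baselines = _lognormal(rng, config.baseline_mean, config.baseline_cv, n)
    spont = rng.random(n) < config.spontaneous_fraction
    times = config.sample_times
    noise_sd = config.noise_sigma * config.gain_mean * config.baseline_mean

    c0_by_region = {
        lab: max(schedule[lab].levels) for lab in schedule.regions
    }
    traces: list[CellTrace] = []
    for i in range(n):
        profile = schedule[labels[i]]
        c0 = c0_by_region[labels[i]]
        if spont[i]:
            # constitutively nuclear: elevated flat ratio, stimulus-independent
            y = np.full_like(times, gains[i])
        elif c0 > 0:
            model = TranslocationModel(tau=taus[i], k=gains[i] / c0)
            y = simulate(model, profile, times).y
        else:
            y = np.zeros_like(times)
        r = baselines[i] * (1.0 + y)
        if config.noise_sigma > 0:
            r = r + rng.normal(0.0, noise_sd, size=times.size)
        r = np.maximum(r, 1e-6)  # ratios are positive by construction
        explant = i // config.cells_per_explant
        traces.append(
            CellTrace(
                cell_id=f"e{explant}c{i % config.cells_per_explant}",
                explant_id=f"e{explant}",
                region=labels[i],
                times=times,
                i_nuc=r * config.cyt_intensity,
                i_cyt=np.full_like(times, config.cyt_intensity),
            )
        )
    truth = GroundTruth(
        cell_ids=tuple(tr.cell_id for tr in traces),
        tau=tuple(float(x) for x in taus),
        gain=tuple(float(x) for x in gains),
        baseline=tuple(float(x) for x in baselines),
        spontaneous=tuple(bool(x) for x in spont),
        region=tuple(labels),
        config=config,
    )
    return traces, truth


@dataclass(frozen=True)
class ImageLayout:
    """Geometry of rendered frames: a grid of round cells with disc nuclei."""

    shape: tuple[int, int] = (256, 256)
    n_slices: int = 5
    cell_radius: int = 14
    nucleus_radius: int = 6
    spacing: int = 36
    guard: int = 3  # perinuclear ring excluded from the cytoplasmic mask
    background: float = 10.0
    defocus_sigma: float = 1.0  # blur per slice of distance from focus
    photons_per_unit: float = 20.0  # shot-noise scale: counts = intensity * gain
    read_noise: float = 1.0

    def positions(self, n_cells: int) -> list[tuple[int, int]]:
        margin = self.spacing // 2 + 2
        rows = []
        y = margin
        while y + margin <= self.shape[0]:
            x = margin
            while x + margin <= self.shape[1]:
                rows.append((y, x))
                x += self.spacing
            y += self.spacing
        if n_cells > len(rows):
            raise LayoutOverflowError(
                f"{n_cells} cells do not fit a {self.shape} frame "
                f"({len(rows)} slots)"
            )
        return rows[:n_cells]


def render_frames(
    traces: list[CellTrace],
    layout: ImageLayout,
    t: float,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Render one time point as a z-stack plus ground-truth masks.

    Cells are non-overlapping discs with concentric disc nuclei; cytoplasm
    pixels carry I_cyt, nuclear pixels I_nuc = R * I_cyt. The central slice
    is in focus; off-center slices are Gaussian-blurred in proportion to
    their distance from focus. With ``noise=True``, Poisson shot noise (at
    ``photons_per_unit`` counts per intensity unit) plus Gaussian read
    noise is applied per pixel. The emitted cytoplasmic masks keep a
    ``guard``-pixel ring off the nuclear envelope, the usual translocation-
    assay precaution against defocus spill-over.

    Returns ``(stack, masks)`` where ``masks[cell_id] = (nuc_mask,
    cyt_mask)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    centers = layout.positions(len(traces))
    focal = np.full(layout.shape, layout.background, dtype=float)
    masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    yy, xx = np.mgrid[0 : layout.shape[0], 0 : layout.shape[1]]
    for tr, (cy, cx) in zip(traces, centers):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell = r2 <= layout.cell_radius**2
        nuc = r2 <= layout.nucleus_radius**2
        # cytoplasmic ROI keeps a guard ring off the nuclear envelope so
        # out-of-focus nuclear light does not bleed into the denominator
        cyt = cell & (r2 > (layout.nucleus_radius + layout.guard) ** 2)
        i_cyt = tr.value_at(t, "i_cyt")
        i_nuc = tr.value_at(t, "i_nuc")
        focal[cyt] = i_cyt
        focal[nuc] = i_nuc
        masks[tr.cell_id] = (nuc, cyt)
    stack = np.empty((layout.n_slices, *layout.shape), dtype=float)
    center = layout.n_slices // 2
    for z in range(layout.n_slices):
        dist = abs(z - center)
        img = (
            focal
            if dist == 0
            else ndimage.gaussian_filter(focal, sigma=layout.defocus_sigma * dist)
        )
        if noise:
            g = layout.photons_per_unit
            img = rng.poisson(np.maximum(img * g, 0.0)).astype(float) / g
            img = img + rng.normal(0.0, layout.read_noise, size=img.shape)
        stack[z] = img
    return stack, masks


def write_dataset(
    path,
    traces: list[CellTrace],
    truth: GroundTruth,
    frames: dict[float, np.ndarray] | None = None,
) -> None:
    """Write traces.csv, truth.json and optional frames/*.tif under ``path``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    write_traces_csv(traces, root / "traces.csv")
    (root / "truth.json").write_text(truth.to_json())
    if frames:
        fdir = root / "frames"
        fdir.mkdir(exist_ok=True)
        for t, stack in frames.items():
            tifffile.imwrite(fdir / f"t{t:07.1f}.tif", stack.astype(np.float32))


def read_dataset(path) -> tuple[list[CellTrace], GroundTruth | None]:
    """Read a dataset directory written by :func:`write_dataset`."""
    root = Path(path)
    csv = root / "traces.csv"
    if not csv.exists():
        raise ParseError(f"no traces.csv under {root}")
    traces = read_traces_csv(csv)
    truth = None
    tj = root / "truth.json"
    if tj.exists():
        truth = GroundTruth.from_json(tj.read_text())
    return traces, truth
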
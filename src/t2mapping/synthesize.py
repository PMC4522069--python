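"""Synthetic multi-echo fixtures with known ground truth.

Two generators cover the study designs the pipeline is validated on:

* :func:`make_phantom` — a cylindrical gel phantom with 12 vials on a
  ring, each vial a disc of uniform (S0, T2, T1); defaults are the
  reference phantom's per-vial (T1, T2) pairs.
* :func:`make_cardiac_sax` — a short-axis left-ventricle slice: annular
  myocardium with per-AHA-segment true T2 (~50-60 ms), a circular blood
  pool with long T2, and empty background, together with the matching
  endo/epicardial contour polygons.

Both corrupt the noiseless decay signal with Rician magnitude noise:
m = sqrt((A + n1)^2 + n2^2) with independent N(0, sigma^2) quadrature
noise, drawn independently per echo.  All randomness flows through an
explicit seed; the same seed reproduces bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import ImageStack
from .segmentation import (
    SEGMENTS_PER_LEVEL,
    ContourPair,
    SegmentLabelMap,
    aha_segments,
    annulus_mask,
    _inside,
)
from .sequences import EchoSchedule
from .reference import gel_phantom_table

__all__ = [
    "VialSpec",
    "CardiacGeometry",
    "GroundTruth",
    "BLOOD_LABEL",
    "add_rician_noise",
    "default_vials",
    "make_phantom",
    "make_cardiac_sax",
    "sigma_for_first_echo_snr",
]

#: label used for the blood pool in cardiac ground-truth label maps
#: (AHA segments are 1..6, background is 0)
BLOOD_LABEL = 100


@dataclass(frozen=True)
class VialSpec:
    """One gel vial: relaxation times, amplitude, and disc geometry."""

    t1: float
    t2: float
    s0: float
    center: tuple[float, float]  # (row, col)
    radius: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0 or self.s0 <= 0 or self.radius <= 0:
            raise ValueError("t1, t2, s0 and radius must all be > 0")


@dataclass
class CardiacGeometry:
    """Geometry and ground truth of one synthetic short-axis slice.

    ``per_segment_t2`` holds the true T2 per AHA segment (6 values for
    basal/mid, 4 for apical).  ``per_segment_sd_inflation`` gives, per
    segment, the SD of a per-pixel multiplicative T2 jitter as a
    fraction of the segment mean; 0 (the default) makes the segment
    perfectly homogeneous, 0.3 manufactures a segment the 20% pixel-SD
    rule must flag.
    """

    center: tuple[float, float] = (48.0, 48.0)
    endo_radius: float = 11.0
    epi_radius: float = 16.0
    rv_insertion_angle: float = 90.0
    slice_level: str = "mid"
    blood_t2: float = 250.0
    blood_t1: float = 1700.0
    myocardium_t1: float = 1000.0
    s0: float = 100.0
    per_segment_t2: list[float] = field(default_factory=lambda: [53.8] * 6)
    per_segment_sd_inflation: list[float] = field(default_factory=lambda: [0.0] * 6)

    def __post_init__(self) -> None:
        if not (self.epi_radius > self.endo_radius > 0):
            raise ValueError("need epi_radius > endo_radius > 0")
        k = SEGMENTS_PER_LEVEL[self.slice_level]
        if len(self.per_segment_t2) != k:
            raise ValueError(
                f"{self.slice_level} slice needs {k} per-segment T2 values, "
                f"got {len(self.per_segment_t2)}"
            )
        if len(self.per_segment_sd_inflation) != k:
            raise ValueError(f"need {k} per-segment SD inflation factors")


@dataclass
class GroundTruth:
    """Pixel-wise generator truth accompanying a synthetic stack."""

    t2_truth: np.ndarray
    s0_truth: np.ndarray
    labels: np.ndarray
    sigma: float
    seed: int


def add_rician_noise(clean, sigma: float, seed: int) -> np.ndarray:
    """Rician-corrupt noiseless amplitudes: |(A + n1) + i n2|."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    clean = np.asarray(clean, dtype=float)
    if sigma == 0:
        return clean.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=clean.shape)
    n2 = rng.normal(0.0, sigma, size=clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2**2)


def _t1_recovery_factor(t1, schedule: EchoSchedule, beta: float, t_rec: float):
    """Optional T2prep shine-through hook: scales amplitudes by
    (1 + beta*exp(-t_rec/T1)).  Off (beta=0) by default; a pure
    generator feature for exploring the direction of T1-dependent
    T2prep overestimation, never part of fitting."""
    if beta == 0.0 or schedule.sequence_name != "T2prep":
        return 1.0
    return 1.0 + beta * np.exp(-t_rec / np.asarray(t1, dtype=float))


def default_vials(
    shape: tuple[int, int] = (128, 128),
    vial_radius: float = 9.0,
    ring_radius: float = 44.0,
    s0: float = 100.0,
) -> list[VialSpec]:
    """The 12 reference vials (T1, T2 pairs) arranged on a ring."""
    table = gel_phantom_table()
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    vials = []
    for i, row in table.iterrows():
        ang = 2 * np.pi * i / len(table)
        c = (center[0] + ring_radius * np.sin(ang), center[1] + ring_radius * np.cos(ang))
        vials.append(
            VialSpec(
                t1=float(row.t1_ms),
                t2=float(row.t2_ref_ms),
                s0=s0,
                center=c,
                radius=vial_radius,
            )
        )
    return vials


def sigma_for_first_echo_snr(
    snr: float, schedule: EchoSchedule, s0: float, t2: float
) -> float:
    """Noise scale giving the requested first-echo SNR.

    SNR is defined as the noiseless first-echo amplitude
    S0*exp(-TE1/T2) divided by the Rician sigma.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return s0 * np.exp(-schedule.times[0] / t2) / snr


def make_phantom(
    vials: list[VialSpec] | None = None,
    schedule: EchoSchedule | None = None,
    sigma: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    shine_through_beta: float = 0.0,
    recovery_time_ms: float = 2500.0,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate the multi-echo stack of a multi-vial gel phantom."""
    if schedule is None:
        raise ValueError("an echo schedule is required")
    if vials is None:
        vials = default_vials(shape)

    for i, a in enumerate(vials):
        for b in vials[i + 1 :]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d <= a.radius + b.radius:
                raise ValueError("vials overlap within the field of view")
        if not (
            a.radius <= a.center[0] <= shape[0] - 1 - a.radius
            and a.radius <= a.center[1] <= shape[1] - 1 - a.radius
        ):
            raise ValueError("vial does not fit inside the image")

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    t2_truth = np.full(shape, np.nan)
    s0_truth = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)
    times = schedule.times_array
    clean = np.zeros(shape + (times.size,))
    for idx, v in enumerate(vials, start=1):
        disc = (rows - v.center[0]) ** 2 + (cols - v.center[1]) ** 2 <= v.radius**2
        labels[disc] = idx
        t2_truth[disc] = v.t2
        s0_truth[disc] = v.s0
        amp = v.s0 * _t1_recovery_factor(v.t1, schedule, shine_through_beta, recovery_time_ms)
        clean[disc, :] = amp * np.exp(-times / v.t2)

    noisy = add_rician_noise(clean, sigma, seed)
    return ImageStack(noisy), GroundTruth(t2_truth, s0_truth, labels, float(sigma), seed)


def _circle_polygon(center: tuple[float, float], radius: float, n: int = 360) -> np.ndarray:
    """Closed circle approximation in (x, y) = (col, row) coordinates."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = center[1] + radius * np.cos(ang)
    y = center[0] + radius * np.sin(ang)
    return np.column_stack([x, y])


def make_cardiac_sax(
    geometry: CardiacGeometry | None = None,
    schedule: EchoSchedule | None = None,
    sigma: float = 0.0,
    shape: tuple[int, int] = (96, 96),
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth, ContourPair]:
    """Simulate one short-axis slice with per-segment myocardial T2.

    Returns the noisy stack, the pixel-wise ground truth, and the
    endo/epi contour polygons whose rasterisation reproduces the
    generator's myocardium mask exactly.
    """
    if schedule is None:
        raise ValueError("an echo schedule is required")
    if geometry is None:
        geometry = CardiacGeometry()
    g = geometry
    max_r = max(abs(g.center[0]), abs(g.center[1]))
    if (
        g.epi_radius >= min(g.center[0], g.center[1], shape[0] - 1 - g.center[0], shape[1] - 1 - g.center[1])
    ):
        raise ValueError("annulus does not fit inside the image")
    del max_r

    contours = ContourPair(
        endo=_circle_polygon(g.center, g.endo_radius),
        epi=_circle_polygon(g.center, g.epi_radius),
    )
    myo = annulus_mask(contours, shape)
    seg: SegmentLabelMap = aha_segments(
        myo, g.center, g.rv_insertion_angle, g.slice_level
    )
    blood = _inside(contours.endo, shape)

    rng = np.random.default_rng(seed)
    t2_truth = np.full(shape, np.nan)
    s0_truth = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)
    t1_map = np.full(shape, g.myocardium_t1)

    labels[blood] = BLOOD_LABEL
    t2_truth[blood] = g.blood_t2
    s0_truth[blood] = g.s0
    t1_map[blood] = g.blood_t1

    for k in range(1, seg.n_segments + 1):
        sel = seg.labels == k
        base = g.per_segment_t2[k - 1]
        infl = g.per_segment_sd_inflation[k - 1]
        if infl > 0:
            vals = rng.normal(base, infl * base, size=int(sel.sum()))
            vals = np.maximum(vals, 1.0)  # T2 stays physical
        else:
            vals = np.full(int(sel.sum()), base)
        t2_truth[sel] = vals
        s0_truth[sel] = g.s0
        labels[sel] = k

    times = schedule.times_array
    region = labels > 0
    clean = np.zeros(shape + (times.size,))
    amp = s0_truth[region][:, None]
    clean[region, :] = amp * np.exp(-times[None, :] / t2_truth[region][:, None])

    noisy = add_rician_noise(clean, sigma, seed + 1)
    truth = GroundTruth(t2_truth, s0_truth, labels, float(sigma), seed)
    return ImageStack(noisy), truth, contours
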
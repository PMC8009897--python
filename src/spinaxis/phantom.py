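"""Synthetic AP spine radiograph phantoms with analytic ground truth.

A phantom is a bright, possibly curved vertebral column on a darker noisy
thorax background. The column midline is a vertical baseline plus a sum of
raised-cosine bumps — smooth, compactly supported and with a closed-form
derivative, so every curvature quantity has an exact analytic value. The
renderer places tilted rectangular vertebral bodies along the midline,
separated by darker disc gaps, and the resulting :class:`PhantomCase`
carries the image together with the true midline, vertebra centroids,
curve segments and per-method angles.

Default geometry mirrors the study population the pipeline targets:
925x475-pixel 8-bit radiographs and 17 thoracolumbar vertebrae (12 thoracic
+ 5 lumbar). Intensity levels (column ~200, background ~60) and the
additive Gaussian noise model are free rendering choices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .axes import MedialAxisSeries, central_sacral_line, displacement
from .curvature import (
    cobb_angle,
    diab_angle,
    ferguson_angle,
    greenspan_index,
)
from .errors import ValidationError
from .landmarks import CurveSegment

__all__ = [
    "CurveSpec",
    "MidlineSpec",
    "PhantomCase",
    "make_midline",
    "midline_slope",
    "analytic_angles",
    "render_radiograph",
    "epsilon_crossing_rows",
    "amplitude_for_cobb",
]

COLUMN_INTENSITY = 200.0
BACKGROUND_INTENSITY = 60.0


@dataclass(frozen=True)
class CurveSpec:
    """One raised-cosine bump of the midline.

    The lateral offset is ``amplitude * (1 + cos(pi*(y - center_row)/half_span))/2``
    inside ``[center_row - half_span, center_row + half_span]`` and zero
    outside: amplitude at the center, zero (with zero slope) at the span
    edges, maximal slope ``pi*amplitude/(2*half_span)`` at the half-span
    inflection points.
    """

    center_row: float
    half_span: float
    amplitude: float

    @property
    def span(self) -> tuple[float, float]:
        return (self.center_row - self.half_span, self.center_row + self.half_span)


@dataclass(frozen=True)
class MidlineSpec:
    """Parametric description of a phantom radiograph."""

    image_height: int = 925
    image_width: int = 475
    baseline_x: float = 237.0
    curves: tuple[CurveSpec, ...] = ()
    n_vertebrae: int = 17
    vertebra_width: int = 50
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        curves = tuple(
            c if isinstance(c, CurveSpec) else CurveSpec(*c) for c in self.curves
        )
        object.__setattr__(self, "curves", curves)
        self._validate()

    def _validate(self) -> None:
        if self.image_height < 40 or self.image_width < 8:
            raise ValidationError("image too small for a phantom")
        if self.n_vertebrae < 2:
            raise ValidationError("need at least 2 vertebrae")
        if self.vertebra_width < 3:
            raise ValidationError("vertebra_width must be >= 3 px")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        for c in self.curves:
            if c.half_span <= 0:
                raise ValidationError("half_span must be positive")
            lo, hi = c.span
            if lo < 0 or hi >= self.image_height:
                raise ValidationError(
                    f"curve span [{lo}, {hi}] exceeds [0, {self.image_height})"
                )
        spans = sorted(c.span for c in self.curves)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo < hi:
                raise ValidationError("curve spans overlap")
        amp = max((abs(c.amplitude) for c in self.curves), default=0.0)
        half_w = self.vertebra_width / 2
        if (
            self.baseline_x - amp - half_w < 0
            or self.baseline_x + amp + half_w > self.image_width - 1
        ):
            raise ValidationError("column leaves the image laterally")


def _midline_at(spec: MidlineSpec, rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    x = np.full(rows.shape, spec.baseline_x, dtype=float)
    for c in spec.curves:
        u = (rows - c.center_row) / c.half_span
        inside = np.abs(u) <= 1.0
        x[inside] += c.amplitude * (1.0 + np.cos(np.pi * u[inside])) / 2.0
    return x


def make_midline(spec: MidlineSpec) -> np.ndarray:
    """True midline x-coordinate at every image row (length image_height)."""
    return _midline_at(spec, np.arange(spec.image_height))


def midline_slope(spec: MidlineSpec, rows: np.ndarray) -> np.ndarray:
    """Closed-form midline derivative dx/dy at the given rows."""
    rows = np.asarray(rows, dtype=float)
    s = np.zeros(rows.shape, dtype=float)
    for c in spec.curves:
        u = (rows - c.center_row) / c.half_span
        inside = np.abs(u) <= 1.0
        s[inside] += (
            -c.amplitude * np.pi / (2.0 * c.half_span) * np.sin(np.pi * u[inside])
        )
    return s


def epsilon_crossing_rows(
    curve: CurveSpec, epsilon: float
) -> tuple[float, float] | None:
    """Rows where the bump's |offset| equals ``epsilon`` (analytic).

    Returns None when the bump never exceeds epsilon. These are the rows at
    which a displacement-threshold detector should open and close the curve.
    """
    a = abs(curve.amplitude)
    if a <= epsilon:
        return None
    u0 = np.arccos(2.0 * epsilon / a - 1.0) / np.pi
    return (
        curve.center_row - u0 * curve.half_span,
        curve.center_row + u0 * curve.half_span,
    )


def _true_segments(spec: MidlineSpec) -> list[tuple[int, int, int]]:
    return [
        (
            int(np.ceil(c.center_row - c.half_span)),
            int(round(c.center_row)),
            int(np.floor(c.center_row + c.half_span)),
        )
        for c in sorted(spec.curves, key=lambda c: c.center_row)
    ]


def analytic_angles(
    midline: np.ndarray,
    segments: list[tuple[int, int, int]],
    half_window: float = 5.0,
    diab_band_height: float | None = None,
) -> list[dict[str, float]]:
    """Ground-truth angles per segment from the exact analytic midline.

    Builds a dense medial axis from the midline and applies the very same
    geometric constructions the curvature module uses on extracted axes
    (CSL anchored at the inferior row), so pipeline estimates are directly
    comparable. The tangent window defaults to a tight 5 rows: on exact
    noise-free data a wide window only adds third-derivative bias at the
    slope extrema (the pipeline's wider default exists to average out
    extraction ripple). Degenerate segments (start == end) are rejected.
    """
    midline = np.asarray(midline, dtype=float)
    ma = MedialAxisSeries(np.arange(len(midline), dtype=float), midline)
    csl = central_sacral_line(ma, anchor="bottom")
    out: list[dict[str, float]] = []
    for start, apex, end in segments:
        if start == end:
            raise ValidationError("degenerate segment: start_row == end_row")
        if start < 0 or end >= len(midline):
            raise ValidationError("segment outside the midline's row range")
        d_apex = midline[apex] - csl.x
        seg = CurveSegment(
            start_row=float(start),
            apex_row=float(apex),
            end_row=float(end),
            direction=int(np.sign(d_apex)) or 1,
            max_displacement=abs(float(d_apex)),
        )
        angles = {
            "cobb": cobb_angle(ma, seg, half_window).value,
            "ferguson": ferguson_angle(
                (seg.start_row, midline[start]),
                (seg.apex_row, midline[apex]),
                (seg.end_row, midline[end]),
            ).value,
            "greenspan": greenspan_index(ma, csl, seg).value,
        }
        try:
            angles["diab"] = diab_angle(ma, seg, diab_band_height).value
        except ValidationError:
            angles["diab"] = float("nan")
        out.append(angles)
    return out


@dataclass
class PhantomCase:
    """Rendered phantom plus its analytic ground truth."""

    image: np.ndarray
    true_midline: np.ndarray
    true_centroids: np.ndarray
    true_angles: list[dict[str, float]]
    true_segments: list[tuple[int, int, int]]
    spec: MidlineSpec
    footprint: np.ndarray = field(repr=False, default=None)

    def truth_dict(self) -> dict:
        """JSON-serializable ground-truth record."""
        return {
            "midline": [
                [int(r), float(x)] for r, x in enumerate(self.true_midline)
            ],
            "centroids": [[float(r), float(x)] for r, x in self.true_centroids],
            "segments": [list(map(int, s)) for s in self.true_segments],
            "angles": [
                {k: float(v) for k, v in a.items()} for a in self.true_angles
            ],
        }


def _vertebra_layout(spec: MidlineSpec) -> tuple[np.ndarray, float]:
    """Evenly spaced vertebra center rows and the body height."""
    pad = round(0.045 * spec.image_height)
    centers = np.linspace(
        pad, spec.image_height - 1 - pad, spec.n_vertebrae
    )
    pitch = (
        (spec.image_height - 1 - 2 * pad) / (spec.n_vertebrae - 1)
        if spec.n_vertebrae > 1
        else spec.image_height - 2 * pad
    )
    gap = max(4.0, 0.15 * pitch)  # intervertebral disc gap
    return centers, pitch - gap


def render_radiograph(spec: MidlineSpec) -> PhantomCase:
    """Render the phantom and populate its ground truth.

    Vertebral bodies are rectangles of width ``vertebra_width`` rotated to
    the local midline tangent (so endplate tilt exists), centered on the
    midline at evenly spaced rows; intensities are ~200 over a ~60
    background with additive Gaussian noise of ``noise_sigma``, clipped to
    [0, 255]. Deterministic given the spec (including its seed).
    """
    h, w = spec.image_height, spec.image_width
    centers, body_h = _vertebra_layout(spec)
    cx = _midline_at(spec, centers)
    slopes = midline_slope(spec, centers)

    foot = np.zeros((h, w), dtype=bool)
    half_w = spec.vertebra_width / 2.0
    half_h = body_h / 2.0
    reach = float(np.hypot(half_h, half_w)) + 1.0
    for r0, x0, s in zip(centers, cx, slopes):
        rlo = max(int(np.floor(r0 - reach)), 0)
        rhi = min(int(np.ceil(r0 + reach)) + 1, h)
        clo = max(int(np.floor(x0 - reach)), 0)
        chi = min(int(np.ceil(x0 + reach)) + 1, w)
        rr, cc = np.ogrid[rlo:rhi, clo:chi]
        dr = rr - r0
        dc = cc - x0
        norm = np.sqrt(1.0 + s * s)
        along = (dr + dc * s) / norm  # component along the spine tangent
        across = (-dr * s + dc) / norm  # component across it
        foot[rlo:rhi, clo:chi] |= (np.abs(along) <= half_h) & (
            np.abs(across) <= half_w
        )

    base = np.where(foot, COLUMN_INTENSITY, BACKGROUND_INTENSITY)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        base = base + rng.normal(0.0, spec.noise_sigma, size=base.shape)
    image = np.clip(np.rint(base), 0, 255).astype(np.uint8)

    midline = make_midline(spec)
    segments = _true_segments(spec)
    angles = analytic_angles(midline, segments)
    centroids = np.stack([centers, cx], axis=1)
    return PhantomCase(
        image=image,
        true_midline=midline,
        true_centroids=centroids,
        true_angles=angles,
        true_segments=segments,
        spec=spec,
        footprint=foot,
    )


def amplitude_for_cobb(
    target_deg: float,
    half_span: float = 200.0,
    center_row: float | None = None,
    image_height: int = 925,
    image_width: int = 475,
    baseline_x: float = 237.0,
    vertebra_width: int = 50,
    half_window: float = 5.0,
) -> float:
    """Bump amplitude whose analytic Cobb angle equals ``target_deg``.

    Solves the (monotone) analytic construction numerically so the returned
    amplitude is exactly consistent with :func:`analytic_angles`. The
    closed-form approximation is Cobb = 2*atan(pi*A/(2*half_span)).
    """
    if center_row is None:
        center_row = image_height / 2.0
    amp_max = image_width - 1 - baseline_x - vertebra_width / 2.0 - 1e-6

    def cobb_of(a: float) -> float:
        spec = MidlineSpec(
            image_height=image_height,
            image_width=image_width,
            baseline_x=baseline_x,
            curves=(CurveSpec(center_row, half_span, a),),
            vertebra_width=vertebra_width,
            noise_sigma=0.0,
        )
        midline = make_midline(spec)
        return analytic_angles(midline, _true_segments(spec), half_window)[0][
            "cobb"
        ]

    if cobb_of(amp_max) < target_deg:
        raise ValidationError(
            f"target {target_deg} deg unreachable within the image width"
        )
    a = float(brentq(lambda a: cobb_of(a) - target_deg, 0.05, amp_max))
    # land on or a hair above the target so downstream band classification
    # of the analytic value is not at the mercy of the root residual
    while cobb_of(a) < target_deg:
        a += 1e-6
    return a
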
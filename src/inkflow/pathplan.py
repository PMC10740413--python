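"""Toolpath planning for pneumatic extrusion printing of hydrogel inks.

Two process refinements specific to pneumatic (pressure-driven) extrusion
are built into the planner:

* **Slow start.**  A pneumatic head has no filament pull-back, so ink lags
  when the nozzle switches from travel to printing and printed strokes
  come out short.  Every printing resumption therefore begins with a short
  segment of length v0 * t0 traversed at the reduced speed v0 (default
  1 mm/s for 0.1 s) before accelerating to the normal print speed; the
  slow segment counts toward the designed stroke length.

* **Fill-to-frame overlap.**  For a perimeter-plus-infill part, the short
  edges of the rectilinear fill stop at a controlled distance D2 from the
  perimeter frame (default 0.3 mm, within the validated 0.2-0.3 mm
  window) so the fill bonds to the frame without over-extruding into it.

Parts are axis-aligned rectangular prisms (or single lines); layers are
stacked in z at the configured layer thickness, the perimeter frame is
printed before the fill, and grid infill alternates 0/90 degrees between
layers.  Extrusion bookkeeping converts a flow rate into per-segment
deposited volume and the expected filament diameter at each segment's
speed.  Export is a minimal G-code dialect (no E axis: pneumatic heads
toggle extrusion with M-codes) that re-imports to an identical path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nozzleflow import filament_diameter

__all__ = [
    "PathConfig",
    "PathSegment",
    "ToolPath",
    "plan_line",
    "plan_grid_prism",
    "extrusion_bookkeeping",
    "export_gcode",
    "import_gcode",
]


@dataclass(frozen=True)
class PathConfig:
    """Printing parameters for the planner.

    Speeds in mm/s, lengths in mm, times in s.  ``overlap_d2_mm`` is the
    distance from a fill line's short edge to the perimeter frame and
    cannot exceed ``frame_margin_mm``, the lateral spacing between frame
    and fill pattern.
    """

    speed_mm_s: float = 12.0
    slow_speed_mm_s: float = 1.0
    slow_time_s: float = 0.1
    travel_speed_mm_s: float = 30.0
    layer_thickness_mm: float = 0.2
    fill_spacing_mm: float = 0.8
    frame_margin_mm: float = 0.5
    overlap_d2_mm: float = 0.3
    nozzle_diameter_mm: float = 0.25

    def __post_init__(self) -> None:
        positives = {
            "speed_mm_s": self.speed_mm_s,
            "slow_speed_mm_s": self.slow_speed_mm_s,
            "travel_speed_mm_s": self.travel_speed_mm_s,
            "layer_thickness_mm": self.layer_thickness_mm,
            "fill_spacing_mm": self.fill_spacing_mm,
            "frame_margin_mm": self.frame_margin_mm,
            "nozzle_diameter_mm": self.nozzle_diameter_mm,
        }
        for name, v in positives.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not (np.isfinite(self.slow_time_s) and self.slow_time_s >= 0):
            raise ValueError(f"slow_time_s must be >= 0, got {self.slow_time_s}")
        if not (0 <= self.overlap_d2_mm <= self.frame_margin_mm):
            raise ValueError(
                f"overlap_d2_mm must lie in [0, frame_margin_mm="
                f"{self.frame_margin_mm}], got {self.overlap_d2_mm}")

    @property
    def slow_length_mm(self) -> float:
        return self.slow_speed_mm_s * self.slow_time_s


@dataclass(frozen=True)
class PathSegment:
    """One straight move: endpoints in mm, speed in mm/s, flags."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    speed_mm_s: float
    extruding: bool
    slow_start: bool = False

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    @property
    def duration_s(self) -> float:
        return self.length_mm / self.speed_mm_s


@dataclass(frozen=True)
class ToolPath:
    """Ordered segments with per-layer grouping (layer index per segment)."""

    segments: tuple[PathSegment, ...]
    layer_of: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        layers = self.layer_of or tuple([0] * len(self.segments))
        if len(layers) != len(self.segments):
            raise ValueError("layer_of must have one entry per segment")
        object.__setattr__(self, "layer_of", tuple(layers))
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.allclose(a.end, b.start, atol=1e-9):
                raise ValueError(f"path not contiguous at {a.end} -> {b.start}")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_layers(self) -> int:
        return max(self.layer_of, default=-1) + 1

    def printing_length_mm(self) -> float:
        return sum(s.length_mm for s in self.segments if s.extruding)

    def printing_time_s(self) -> float:
        return sum(s.duration_s for s in self.segments if s.extruding)


def _snap(xyz) -> tuple[float, float, float]:
    """Round coordinates to 1 nm so exported decimals re-import exactly."""
    return tuple(float(round(float(c), 9)) for c in xyz)


class _Builder:
    """Accumulates contiguous segments, inserting slow starts automatically."""

    def __init__(self, origin, config: PathConfig):
        self.pos = _snap(origin)
        self.cfg = config
        self.segs: list[PathSegment] = []
        self.layers: list[int] = []
        self.layer = 0
        self._was_printing = False

    def travel_to(self, xyz) -> None:
        end = _snap(xyz)
        if np.allclose(end, self.pos, atol=1e-12):
            return
        self.segs.append(PathSegment(self.pos, end, self.cfg.travel_speed_mm_s,
                                     extruding=False))
        self.layers.append(self.layer)
        self.pos = end
        self._was_printing = False

    def print_to(self, xyz) -> None:
        end = _snap(xyz)
        vec = np.subtract(end, self.pos)
        length = float(np.linalg.norm(vec))
        if length == 0.0:
            return
        slow = self.cfg.slow_length_mm
        if not self._was_printing and slow > 0.0:
            if length <= slow:
                raise ValueError(
                    f"stroke of {length} mm is shorter than the slow-start "
                    f"segment ({slow} mm)")
            mid = _snap(np.asarray(self.pos) + vec * (slow / length))
            self.segs.append(PathSegment(self.pos, mid, self.cfg.slow_speed_mm_s,
                                         extruding=True, slow_start=True))
            self.layers.append(self.layer)
            self.pos = mid
        self.segs.append(PathSegment(self.pos, end, self.cfg.speed_mm_s,
                                     extruding=True))
        self.layers.append(self.layer)
        self.pos = end
        self._was_printing = True

    def build(self) -> ToolPath:
        return ToolPath(tuple(self.segs), tuple(self.layers))


def plan_line(length_mm: float, config: PathConfig | None = None) -> ToolPath:
    """Plan a single straight stroke of the given design length.

    The first v0*t0 of the stroke is printed at the slow-start speed, the
    remainder at the normal speed; the total path length equals the design
    length.  With t0 = 0 the stroke is a single normal-speed segment.
    """
    config = config or PathConfig()
    if length_mm <= config.slow_length_mm:
        raise ValueError(
            f"design length {length_mm} mm must exceed the slow-start "
            f"length {config.slow_length_mm} mm")
    b = _Builder((0.0, 0.0, 0.0), config)
    b.print_to((length_mm, 0.0, 0.0))
    return b.build()


def plan_grid_prism(width_mm: float, depth_mm: float, layers: int,
                    config: PathConfig | None = None,
                    pattern: str = "grid") -> ToolPath:
    """Plan a rectangular prism: perimeter frame first, then rectilinear fill.

    The frame traces the part outline; fill lines are spaced
    ``fill_spacing_mm`` apart, inset laterally by ``frame_margin_mm`` from
    the frame, and their short edges stop ``overlap_d2_mm`` short of the
    frame.  ``pattern='grid'`` rotates the fill 90 degrees on alternate
    layers (0/90 infill); ``pattern='solid'`` keeps one orientation.
    Every printing resumption gets a slow-start segment.
    """
    config = config or PathConfig()
    if pattern not in ("grid", "solid"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if layers < 1:
        raise ValueError("need at least one layer")
    if width_mm <= 2 * config.frame_margin_mm or depth_mm <= 2 * config.frame_margin_mm:
        raise ValueError(
            f"part {width_mm} x {depth_mm} mm too small for frame margin "
            f"{config.frame_margin_mm} mm")

    b = _Builder((0.0, 0.0, 0.0), config)
    for layer in range(layers):
        b.layer = layer
        z = layer * config.layer_thickness_mm
        # perimeter frame, counter-clockwise from the origin corner
        b.travel_to((0.0, 0.0, z))
        for corner in ((width_mm, 0.0, z), (width_mm, depth_mm, z),
                       (0.0, depth_mm, z), (0.0, 0.0, z)):
            b.print_to(corner)
        # rectilinear fill; 0 deg = lines along x
        along_x = True if pattern == "solid" else (layer % 2 == 0)
        if along_x:
            run_lo, run_hi = config.overlap_d2_mm, width_mm - config.overlap_d2_mm
            lateral_span = depth_mm
        else:
            run_lo, run_hi = config.overlap_d2_mm, depth_mm - config.overlap_d2_mm
            lateral_span = width_mm
        lat_lo = config.frame_margin_mm
        lat_hi = lateral_span - config.frame_margin_mm
        n_lines = int(np.floor((lat_hi - lat_lo) / config.fill_spacing_mm)) + 1
        for i in range(n_lines):
            lat = lat_lo + i * config.fill_spacing_mm
            x0, x1 = (run_lo, run_hi) if i % 2 == 0 else (run_hi, run_lo)
            if along_x:
                b.travel_to((x0, lat, z))
                b.print_to((x1, lat, z))
            else:
                b.travel_to((lat, x0, z))
                b.print_to((lat, x1, z))
    return b.build()


def extrusion_bookkeeping(path: ToolPath, q_ul_s: float) -> pd.DataFrame:
    """Per-segment deposited volume and predicted filament diameter.

    At constant flow rate Q, a printing segment of duration t deposits
    Q*t uL of ink; the expected filament diameter follows the
    volume-conservation relation d = 2*sqrt(Q/(pi*v)) at the segment's
    speed.  Travel segments deposit nothing.  Summed volumes equal
    Q x total printing time exactly.
    """
    if q_ul_s <= 0:
        raise ValueError(f"flow rate must be > 0, got {q_ul_s}")
    rows = []
    for k, seg in enumerate(path.segments):
        vol = q_ul_s * seg.duration_s if seg.extruding else 0.0
        dia = filament_diameter(q_ul_s, seg.speed_mm_s) if seg.extruding else np.nan
        rows.append({
            "segment": k, "layer": path.layer_of[k],
            "length_mm": seg.length_mm, "speed_mm_s": seg.speed_mm_s,
            "extruding": seg.extruding, "slow_start": seg.slow_start,
            "duration_s": seg.duration_s, "volume_ul": vol,
            "filament_diameter_mm": dia,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# G-code export / import
# ---------------------------------------------------------------------------
# Minimal dialect for pneumatic printers (no E axis): G0 travel, G1 print,
# F feed in mm/min, M101/M103 extrusion on/off, comments marking layers and
# slow-start segments.

_HEADER = ["; inkflow toolpath", "G21 ; mm", "G90 ; absolute"]
_FOOTER = ["M103 ; extrusion off", "; end"]


def _fmt(v: float) -> str:
    return f"{v:.9f}".rstrip("0").rstrip(".")


def export_gcode(path: ToolPath, file) -> None:
    """Write the toolpath to ``file`` (path or file-like) as G-code."""
    lines = list(_HEADER)
    if len(path):
        x, y, z = path.segments[0].start
        lines.append(f"G0 X{_fmt(x)} Y{_fmt(y)} Z{_fmt(z)}")
    extruding = False
    last_layer = None
    for seg, layer in zip(path.segments, path.layer_of):
        if layer != last_layer:
            lines.append(f"; layer {layer}")
            last_layer = layer
        if seg.extruding and not extruding:
            lines.append("M101 ; extrusion on")
            extruding = True
        elif not seg.extruding and extruding:
            lines.append("M103 ; extrusion off")
            extruding = False
        cmd = "G1" if seg.extruding else "G0"
        x, y, z = seg.end
        feed = seg.speed_mm_s * 60.0
        tag = " ; slow-start" if seg.slow_start else ""
        lines.append(f"{cmd} X{_fmt(x)} Y{_fmt(y)} Z{_fmt(z)} F{_fmt(feed)}{tag}")
    lines.extend(_FOOTER)
    text = "\n".join(lines) + "\n"
    if hasattr(file, "write"):
        file.write(text)
    else:
        with open(file, "w", encoding="utf-8") as fh:
            fh.write(text)


def import_gcode(file) -> ToolPath:
    """Re-read a file written by :func:`export_gcode` into a ToolPath."""
    if hasattr(file, "read"):
        text = file.read()
    else:
        with open(file, encoding="utf-8") as fh:
            text = fh.read()
    segs: list[PathSegment] = []
    layers: list[int] = []
    pos: tuple[float, float, float] | None = None
    layer = 0
    first_move = True
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("; layer "):
            layer = int(line.split()[2])
            continue
        if not line or line.startswith(";") or line.startswith("M") or line.startswith("G2"):
            continue
        if line.startswith("G90"):
            continue
        if line.startswith(("G0 ", "G1 ")):
            slow = "slow-start" in line
            body = line.split(";")[0]
            parts = dict((w[0], float(w[1:])) for w in body.split()[1:])
            end = (parts["X"], parts["Y"], parts["Z"])
            if first_move and "F" not in parts:
                pos = end          # initial positioning move
                first_move = False
                continue
            first_move = False
            if pos is None:
                pos = end
                continue
            speed = parts["F"] / 60.0
            segs.append(PathSegment(pos, end, speed,
                                    extruding=body.startswith("G1"),
                                    slow_start=slow))
            layers.append(layer)
            pos = end
    return ToolPath(tuple(segs), tuple(layers))
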
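"""End-to-end orchestration: frame stacks in, contours/metrics/mesh out.

``run_pullback`` reads an ordered PNG/TIFF stack, segments every frame
(per-frame failures are flagged, never fatal), writes per-frame contour
CSV/JSON and a metrics table, and lofts the segmented contours into an
STL mesh.  ``run_phantom_suite`` is the validation entry point: it
generates a synthetic pullback with analytic ground truth, segments it,
and reports Bland–Altman/regression agreement against the truth.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import phantom as ph
from .agreement import AgreementReport, agreement_report, plot_agreement, report_to_text
from .agreement import PairedSeries
from .contour import LumenContour, SegmentationConfig, segment_frame
from .morphometry import LumenMetrics, frame_metrics, polygon_metrics
from .preprocess import FrameImage, PreprocessConfig, to_grayscale
from .reconstruct import export_mesh, loft_mesh, stack_contours

__all__ = ["RunConfig", "RunManifest", "run_pullback", "run_phantom_suite",
           "load_config_file", "read_frames", "write_contours_csv",
           "read_contours_csv"]

CONTOUR_SAMPLES = 720


@dataclass
class RunConfig:
    """Flat configuration for a pullback run.

    ``catheter_center`` is either the string ``"image_center"`` or an
    (x, y) pixel pair applied to every frame.
    """

    input: str = ""
    mm_per_px: float = 0.01
    catheter_center: object = "image_center"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    frame_spacing_mm: float = 0.2
    ring_samples: int = 120
    cap_ends: bool = True
    output_dir: str = "octlumen_out"
    seed: int = 0
    log_level: str = "info"

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    frames: list = field(default_factory=list)  # {index, source, status, reason}
    timings: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"frames": self.frames, "timings": self.timings,
                       "config": self.config, "outputs": self.outputs}, fh,
                      indent=1, default=str)


# Keys accepted in the flat key=value config file, mapped onto RunConfig
# and its sub-configs.  Every printed algorithm constant appears here
# with its default.
_PRE_KEYS = {"median_kernel": int, "morph_kernel": int, "binarize_threshold": int,
             "canny_sigma": float, "canny_low": float, "canny_high": float}
_SEG_KEYS = {"n_domains": int, "domain_width_deg": float, "min_edge_count": int,
             "min_knot_spacing_mm": float, "max_curvature_per_mm": float,
             "center_mask_radius_mm": float, "min_knots_for_fit": int}
_TOP_KEYS = {"input": str, "mm_per_px": float, "frame_spacing_mm": float,
             "ring_samples": int, "cap_ends": lambda s: s.lower() in ("1", "true", "yes"),
             "output_dir": str, "seed": int, "log_level": str}


def load_config_file(path, base: RunConfig | None = None) -> RunConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    cfg = base or RunConfig()
    pre = dataclasses.asdict(cfg.preprocess)
    seg = dataclasses.asdict(cfg.segmentation)
    top: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in _PRE_KEYS:
            pre[key] = _PRE_KEYS[key](val)
        elif key in _SEG_KEYS:
            seg[key] = _SEG_KEYS[key](val)
        elif key in _TOP_KEYS:
            top[key] = _TOP_KEYS[key](val)
        elif key == "catheter_center":
            if val == "image_center":
                top["catheter_center"] = val
            else:
                x, y = (float(v) for v in val.split(","))
                top["catheter_center"] = (x, y)
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return dataclasses.replace(cfg, preprocess=PreprocessConfig(**pre),
                               segmentation=SegmentationConfig(**seg), **top)


def read_frames(config: RunConfig) -> tuple[list[FrameImage], list[str]]:
    """Read an ordered PNG/TIFF frame stack; returns (frames, source paths)."""
    src = Path(config.input)
    if src.is_dir():
        paths = sorted(p for p in src.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
    elif src.is_file():
        paths = [src]
    else:
        raise FileNotFoundError(f"input not found: {src}")
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF frames in {src}")
    frames = []
    for p in paths:
        arr = iio.imread(p)
        center = None if config.catheter_center == "image_center" else tuple(
            config.catheter_center)
        frames.append(to_grayscale(arr, mm_per_px=config.mm_per_px,
                                   catheter_center=center))
    return frames, [str(p) for p in paths]


def write_contours_csv(contours: dict[int, LumenContour], path,
                       n_samples: int = CONTOUR_SAMPLES) -> None:
    """Fixed-sampling contour table: frame_index, point_index, x_mm, y_mm."""
    rows = []
    for idx in sorted(contours):
        xy = contours[idx].sample(n_samples)
        for j, (x, y) in enumerate(xy):
            rows.append((idx, j, x, y))
    pd.DataFrame(rows, columns=["frame_index", "point_index", "x_mm", "y_mm"]).to_csv(
        path, index=False, float_format="%.6f")


def read_contours_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {int(i): g.sort_values("point_index")[["x_mm", "y_mm"]].to_numpy()
            for i, g in df.groupby("frame_index")}


def _contour_json(idx: int, contour: LumenContour, diag) -> dict:
    return {
        "frame_index": idx,
        "degree": int(contour.degree),
        "control_points": contour.control_points.tolist(),
        "knot_vector": contour.knot_vector.tolist(),
        "weights": contour.weights.tolist(),
        "diagnostics": dataclasses.asdict(diag),
    }


def _segment_stack(frames, config: RunConfig):
    contours: dict[int, LumenContour] = {}
    diags = {}
    metrics: dict[int, LumenMetrics] = {}
    for i, frame in enumerate(frames):
        t0 = time.perf_counter()
        contour, diag = segment_frame(frame, config.segmentation, config.preprocess)
        diags[i] = (diag, time.perf_counter() - t0)
        if contour is not None:
            contours[i] = contour
            metrics[i] = frame_metrics(contour)
    return contours, metrics, diags


def _write_outputs(frames, sources, contours, metrics, diags, config: RunConfig):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot())
    for i in range(len(frames)):
        diag, dt = diags[i]
        status = "flagged" if i not in contours else "segmented"
        manifest.frames.append({"index": i, "source": sources[i], "status": status,
                                "reason": diag.reason, "seconds": round(dt, 4)})
    write_contours_csv(contours, out / "contours.csv")
    manifest.outputs.append("contours.csv")
    with open(out / "contours.json", "w") as fh:
        json.dump([_contour_json(i, contours[i], diags[i][0]) for i in sorted(contours)],
                  fh, indent=1)
    manifest.outputs.append("contours.json")
    rows = [(i, m.area, m.d_min, m.d_max, m.d_mean) for i, m in sorted(metrics.items())]
    pd.DataFrame(rows, columns=["frame_index", "area_mm2", "dmin_mm", "dmax_mm",
                                "dmean_mm"]).to_csv(out / "metrics.csv", index=False,
                                                    float_format="%.6f")
    manifest.outputs.append("metrics.csv")
    if len(contours) >= 2:
        model = stack_contours([contours[i] for i in sorted(contours)],
                               config.frame_spacing_mm)
        mesh = loft_mesh(model, ring_samples=config.ring_samples,
                         cap_ends=config.cap_ends)
        export_mesh(mesh, "stl", out / "lumen.stl")
        manifest.outputs.append("lumen.stl")
    manifest.timings = {
        "segment_total_s": round(sum(dt for _, dt in diags.values()), 4),
        "per_frame_mean_s": round(float(np.mean([dt for _, dt in diags.values()])), 4),
    }
    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def run_pullback(config: RunConfig) -> RunManifest:
    """Segment an on-disk frame stack and write all artifacts.

    Per-frame failures are flagged in the manifest and excluded from the
    mesh; a run with no segmentable frame raises ``RuntimeError``.
    """
    frames, sources = read_frames(config)
    contours, metrics, diags = _segment_stack(frames, config)
    if not contours:
        raise RuntimeError("no segmentable frames in input")
    return _write_outputs(frames, sources, contours, metrics, diags, config)


def _write_phantom_inputs(frames, truths, out: Path) -> list[str]:
    frame_dir = out / "frames"
    frame_dir.mkdir(parents=True, exist_ok=True)
    sources = []
    gt_rows, contour_rows = [], []
    for i, (frame, gt) in enumerate(zip(frames, truths)):
        p = frame_dir / f"frame_{i:04d}.png"
        iio.imwrite(p, frame.pixels)
        sources.append(str(p))
        gt_rows.append((i, gt.area, gt.d_min, gt.d_max, gt.d_mean))
        step = max(1, len(gt.theta_deg) // 360)
        for th, r in zip(gt.theta_deg[::step], gt.r_mm[::step]):
            contour_rows.append((i, th, r))
    pd.DataFrame(gt_rows, columns=["frame_index", "area_mm2", "dmin_mm", "dmax_mm",
                                   "dmean_mm"]).to_csv(out / "ground_truth.csv",
                                                       index=False, float_format="%.6f")
    pd.DataFrame(contour_rows, columns=["frame_index", "theta_deg", "r_mm"]).to_csv(
        out / "ground_truth_contours.csv", index=False, float_format="%.6f")
    return sources


def run_phantom_suite(
    seed: int,
    n_frames: int = 50,
    out_dir: str | Path = "phantom_out",
    config: RunConfig | None = None,
    plots: bool = False,
) -> tuple[RunManifest, dict[str, AgreementReport]]:
    """Generate, segment, and score the default phantom validation suite."""
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3")
    config = config or RunConfig()
    config = dataclasses.replace(config, seed=seed, output_dir=str(out_dir))
    out = Path(out_dir)
    specs = ph.default_suite_specs(n_frames, seed=seed)
    frames, truths = ph.synth_pullback(n_frames, specs, seed=seed)
    sources = _write_phantom_inputs(frames, truths, out)
    contours, metrics, diags = _segment_stack(frames, config)
    manifest = _write_outputs(frames, sources, contours, metrics, diags, config)
    gt_metrics = [
        LumenMetrics(area=gt.area, d_min=gt.d_min, d_max=gt.d_max, d_mean=gt.d_mean,
                     centroid=(0.0, 0.0), n_samples=len(gt.theta_deg))
        for gt in truths
    ]
    flags = [i not in contours for i in range(n_frames)]
    reports = agreement_report([metrics.get(i, gt_metrics[i]) for i in range(n_frames)],
                               gt_metrics, exclude_flags=flags)
    rows = [(r.metric_name, r.units, r.n, r.bias, r.sd_diff, r.loa_low, r.loa_high,
             r.slope, r.intercept, r.r, r.r_squared, r.p_value)
            for r in reports.values()]
    pd.DataFrame(rows, columns=["metric", "units", "n", "bias", "sd_diff", "loa_low",
                                "loa_high", "slope", "intercept", "r", "r_squared",
                                "p_value"]).to_csv(out / "agreement.csv", index=False,
                                                   float_format="%.6g")
    (out / "agreement.txt").write_text(
        "".join(report_to_text(r) for r in reports.values()))
    if plots:
        keep = [i for i in range(n_frames) if not flags[i]]
        for attr, rep in reports.items():
            series = PairedSeries(
                proposed=np.array([getattr(metrics[i], attr) for i in keep]),
                reference=np.array([getattr(gt_metrics[i], attr) for i in keep]),
                metric_name=attr, units=rep.units)
            plot_agreement(series, out / f"agreement_{attr}.png")
    return manifest, reports
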
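"""Synthetic scene recordings for end-to-end testing without real data.

The generator emulates the structure of a desk-scale lab scene viewed by a
head-mounted camera: K rectangular AOIs on a textured background,
including left/right twin pairs that share an identical appearance (the
hard case for appearance-based classification), per-frame translation
jitter standing in for head movement, and a fixation stream with
geometric dwell runs, ~60% background fixations and 200–400 ms durations.
Defaults mirror the reference study setup: 7 AOIs (1 single + 3 twin
pairs), an initial pool of 10 patches per class, and an 870-fixation
annotation task split into phases of 646 and 224.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (AOISchema, ArrayFrames, FixationRecord, FramesSource,
                 extract_patch, write_fixation_table)
from .fewshot import LabeledPool

__all__ = [
    "Texture", "Region", "SceneSpec", "SyntheticBenchmark",
    "build_scene", "render_frame", "sample_fixation_stream",
    "make_benchmark", "point_label", "write_benchmark", "read_benchmark",
    "SceneFrames",
]

#: background fixations stay at least this far (px) from any AOI rectangle
BG_MARGIN = 8


@dataclass(frozen=True)
class Texture:
    base_color: tuple            # RGB, 0-255
    noise: float = 8.0           # Gaussian pixel noise sigma
    pattern: str = "flat"        # flat | stripes | checker
    pattern_color: tuple = (0, 0, 0)
    period: int = 8


@dataclass(frozen=True)
class Region:
    name: str
    rect: tuple                  # (x0, y0, w, h) in image coordinates
    texture: Texture

    def contains(self, x: int, y: int, margin: int = 0) -> bool:
        x0, y0, w, h = self.rect
        return (x0 - margin <= x < x0 + w + margin
                and y0 - margin <= y < y0 + h + margin)


@dataclass(frozen=True)
class SceneSpec:
    width: int
    height: int
    regions: tuple
    background: Texture
    jitter_px: int = 2
    twin_groups: tuple = ()

    def __post_init__(self):
        for reg in self.regions:
            x0, y0, w, h = reg.rect
            if not (0 <= x0 and 0 <= y0 and x0 + w <= self.width and y0 + h <= self.height):
                raise ValueError(f"region {reg.name} outside canvas")
        for a in self.regions:
            for b in self.regions:
                if a.name < b.name and _overlap(a.rect, b.rect):
                    raise ValueError(f"regions {a.name} and {b.name} overlap")

    @property
    def aoi_names(self) -> tuple:
        return tuple(r.name for r in self.regions)

    def schema(self, bg_name: str = "BG") -> AOISchema:
        return AOISchema(self.aoi_names, bg_name)

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def collapse_mapping(self) -> dict:
        """Many-to-one map merging each twin pair into its summary class."""
        out = {}
        for group in self.twin_groups:
            summary = _common_prefix(group)
            for name in group:
                out[name] = summary
        return out


def _overlap(a, b) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


def _common_prefix(names: Sequence[str]) -> str:
    import os
    pref = os.path.commonprefix(list(names)).rstrip("_")
    return pref or "+".join(names)


def _palette(n: int, similarity: float, rng) -> list:
    """n distinct base colors; similarity in [0,1] pulls them together."""
    colors = []
    for i in range(n):
        hue = (i / n + 0.05) % 1.0
        r, g, b = colorsys.hsv_to_rgb(hue, 0.75, 0.85)
        colors.append(np.array([r, g, b]) * 255.0)
    mean = np.mean(colors, axis=0)
    return [tuple(float(v) for v in (1 - similarity) * c + similarity * mean)
            for c in colors]


def build_scene(k_singles: int = 1, k_twin_pairs: int = 3,
                similarity: float = 0.0, seed: int = 0,
                width: int = 480, height: int = 360,
                jitter_px: int = 2) -> SceneSpec:
    """Deterministic scene with twin pairs on the left/right flanks and
    singles down the middle; ``similarity`` moves non-twin textures toward
    one another (0 = maximally distinct)."""
    rng = np.random.default_rng([seed, 101])
    n_tex = k_singles + k_twin_pairs
    if n_tex < 1:
        raise ValueError("need at least one AOI")
    colors = _palette(n_tex, similarity, rng)
    patterns = ["stripes", "checker", "flat"]
    textures = [Texture(base_color=colors[i], noise=8.0,
                        pattern=patterns[i % 3],
                        pattern_color=tuple(0.55 * float(v) for v in colors[i]),
                        period=6 + 2 * (i % 3))
                for i in range(n_tex)]

    def column_rects(n, x0, w):
        if n == 0:
            return []
        gap = 20
        h = min(72, (height - gap * (n + 1)) // max(n, 1))
        ys = [gap + i * (h + gap) for i in range(n)]
        return [(x0, y, w, h) for y in ys]

    rw = width // 5
    regions = []
    twin_groups = []
    left = column_rects(k_twin_pairs, 20, rw)
    right = column_rects(k_twin_pairs, width - 20 - rw, rw)
    for i in range(k_twin_pairs):
        tex = textures[i]
        l_name, r_name = f"pair{i + 1}_L", f"pair{i + 1}_R"
        regions.append(Region(l_name, left[i], tex))
        regions.append(Region(r_name, right[i], tex))
        twin_groups.append((l_name, r_name))
    mid = column_rects(k_singles, (width - rw) // 2, rw)
    for i in range(k_singles):
        regions.append(Region(f"obj{i + 1}", mid[i], textures[k_twin_pairs + i]))
    background = Texture(base_color=(120.0, 120.0, 120.0), noise=8.0)
    return SceneSpec(width=width, height=height, regions=tuple(regions),
                     background=background, jitter_px=jitter_px,
                     twin_groups=tuple(twin_groups))


def _fill_texture(canvas: np.ndarray, rect, tex: Texture, rng) -> None:
    x0, y0, w, h = rect
    h_img, w_img = canvas.shape[:2]
    xa, ya = max(x0, 0), max(y0, 0)
    xb, yb = min(x0 + w, w_img), min(y0 + h, h_img)
    if xb <= xa or yb <= ya:
        return
    block = np.empty((yb - ya, xb - xa, 3))
    block[:] = np.asarray(tex.base_color)
    if tex.pattern != "flat":
        yy, xx = np.mgrid[ya - y0:yb - y0, xa - x0:xb - x0]
        if tex.pattern == "stripes":
            mask = (yy // tex.period) % 2 == 0
        else:
            mask = ((yy // tex.period) + (xx // tex.period)) % 2 == 0
        block[mask] = np.asarray(tex.pattern_color)
    block += rng.normal(0.0, tex.noise, size=block.shape)
    canvas[ya:yb, xa:xb] = block


def render_frame(scene: SceneSpec, frame_index: int, seed: int = 0) -> np.ndarray:
    """Render one frame: background, then jitter-shifted AOI rectangles,
    all with seeded pixel noise.  Pure function of (scene, index, seed).

    The noise field depends on the seed only; the per-frame jitter offset
    is what varies across frames, so zero jitter gives identical frames.
    """
    rng = np.random.default_rng([seed, 977])
    canvas = np.empty((scene.height, scene.width, 3))
    _fill_texture(canvas, (0, 0, scene.width, scene.height), scene.background, rng)
    if scene.jitter_px > 0:
        jitter_rng = np.random.default_rng([seed, 977, frame_index])
        dx, dy = jitter_rng.integers(-scene.jitter_px, scene.jitter_px + 1, size=2)
    else:
        dx = dy = 0
    for reg in scene.regions:
        x0, y0, w, h = reg.rect
        _fill_texture(canvas, (x0 + dx, y0 + dy, w, h), reg.texture, rng)
    return np.clip(canvas, 0, 255).astype(np.uint8)


class SceneFrames(FramesSource):
    """Lazy frame provider rendering (and caching) synthetic frames."""

    def __init__(self, scene: SceneSpec, n_frames: int, seed: int = 0):
        self.scene = scene
        self.n_frames = n_frames
        self.seed = seed
        self.width = scene.width
        self.height = scene.height
        self._cache: dict = {}

    def get_frame(self, index: int) -> np.ndarray:
        self._check_index(index)
        if index not in self._cache:
            self._cache[index] = render_frame(self.scene, index, self.seed)
            if len(self._cache) > 64:
                self._cache.pop(next(iter(self._cache)))
        return self._cache[index]


def point_label(scene: SceneSpec, x_px: int, y_px: int, bg_name: str = "BG") -> str:
    """Ground-truth oracle: name of the region containing a pixel, else
    the background label."""
    for reg in scene.regions:
        if reg.contains(x_px, y_px):
            return reg.name
    return bg_name


def _pixel_to_norm(x: int, y: int, width: int, height: int) -> tuple:
    return x / (width - 1), 1.0 - y / (height - 1)


def _sample_point_in_region(reg: Region, rng, margin: int = 6) -> tuple:
    x0, y0, w, h = reg.rect
    m = min(margin, (w - 1) // 2, (h - 1) // 2)
    x = int(rng.integers(x0 + m, x0 + w - m))
    y = int(rng.integers(y0 + m, y0 + h - m))
    return x, y


def _sample_bg_point(scene: SceneSpec, rng) -> tuple:
    for _ in range(10_000):
        x = int(rng.integers(0, scene.width))
        y = int(rng.integers(0, scene.height))
        if not any(r.contains(x, y, margin=BG_MARGIN) for r in scene.regions):
            return x, y
    raise RuntimeError("could not place a background fixation; scene too crowded")


def sample_fixation_stream(scene: SceneSpec, n: int, bg_fraction: float = 0.6,
                           mean_dwell_run: float = 3.0,
                           duration_range_ms: tuple = (200.0, 400.0),
                           seed: int = 0, start_frame: int = 0,
                           start_id: int = 0, start_ts: float = 0.0,
                           bg_name: str = "BG", phase: str | None = None) -> list:
    """Fixation stream with ground truth: geometric dwell runs alternate
    between AOIs and background so the background share converges to
    ``bg_fraction``; positions are sampled inside the labeled region (or
    the background margin zone); durations are uniform in the given range.

    Returns a list of ``(FixationRecord, true_label)``; frame indices
    advance by one per fixation.
    """
    if n < 0 or not 0.0 <= bg_fraction <= 1.0:
        raise ValueError("invalid stream parameters")
    if n > 0 and not scene.regions and bg_fraction < 1.0:
        raise ValueError("cannot sample AOI fixations from an empty scene")
    rng = np.random.default_rng([seed, 523])
    out = []
    t = start_ts
    fid = start_id
    frame = start_frame
    p_run = min(1.0, 1.0 / max(mean_dwell_run, 1.0))
    while len(out) < n:
        if rng.random() < bg_fraction or not scene.regions:
            label = bg_name
        else:
            label = scene.regions[int(rng.integers(len(scene.regions)))].name
        run = int(rng.geometric(p_run))
        for _ in range(min(run, n - len(out))):
            if label == bg_name:
                x, y = _sample_bg_point(scene, rng)
            else:
                x, y = _sample_point_in_region(scene.region(label), rng)
            nx, ny = _pixel_to_norm(x, y, scene.width, scene.height)
            dur = float(rng.uniform(*duration_range_ms))
            out.append((FixationRecord(fixation_id=fid, start_ts=t,
                                       duration_ms=dur, norm_x=nx, norm_y=ny,
                                       frame_index=frame, phase=phase),
                        label))
            t += dur / 1000.0 + 0.05     # fixation plus a short saccade gap
            fid += 1
            frame += 1
    return out


@dataclass
class SyntheticBenchmark:
    """Everything a simulated annotation study needs, reproducible from
    (scene, seed): initial pool, phase-tagged task stream, held-out
    evaluation stream, and ground truth for both."""

    scene: SceneSpec
    schema: AOISchema
    frames: FramesSource
    pool: LabeledPool
    task_fixations: list
    task_labels: list
    eval_fixations: list
    eval_labels: list
    seed: int
    patch_size: int


def make_benchmark(scene: SceneSpec, seed: int = 0, n_pool: int = 10,
                   task_phases: tuple = (("exp_1", 646), ("exp_2", 224)),
                   n_eval: int = 300, patch_size: int = 32,
                   bg_fraction: float = 0.6, mean_dwell_run: float = 3.0,
                   bg_name: str = "BG") -> SyntheticBenchmark:
    """Build the full benchmark: 10 patches per class by default, a task
    stream of 646 + 224 fixations, and a disjoint evaluation stream."""
    schema = scene.schema(bg_name)
    n_task = sum(n for _, n in task_phases)
    n_pool_frames = n_pool * len(scene.regions)
    frames = SceneFrames(scene, n_task + n_eval + n_pool_frames, seed=seed)

    task = []
    for i, (phase, n_phase) in enumerate(task_phases):
        start = len(task)
        task.extend(sample_fixation_stream(
            scene, n_phase, bg_fraction=bg_fraction, mean_dwell_run=mean_dwell_run,
            seed=seed * 10 + i, start_frame=start, start_id=start,
            start_ts=0.0 if not task else task[-1][0].start_ts + 1.0,
            bg_name=bg_name, phase=phase))
    eval_stream = sample_fixation_stream(
        scene, n_eval, bg_fraction=bg_fraction, mean_dwell_run=mean_dwell_run,
        seed=seed * 10 + 7, start_frame=n_task, start_id=n_task,
        bg_name=bg_name, phase="eval")

    rng = np.random.default_rng([seed, 31])
    pool = LabeledPool(schema)
    frame = n_task + n_eval
    for reg in scene.regions:
        for _ in range(n_pool):
            x, y = _sample_point_in_region(reg, rng)
            nx, ny = _pixel_to_norm(x, y, scene.width, scene.height)
            fx = FixationRecord(fixation_id=10_000_000 + frame, start_ts=float(frame),
                                duration_ms=300.0, norm_x=nx, norm_y=ny,
                                frame_index=frame)
            pool.add(reg.name, extract_patch(frames, fx, patch_size))
            frame += 1
    pool.mark_fitted()

    return SyntheticBenchmark(
        scene=scene, schema=schema, frames=frames, pool=pool,
        task_fixations=[f for f, _ in task], task_labels=[lab for _, lab in task],
        eval_fixations=[f for f, _ in eval_stream],
        eval_labels=[lab for _, lab in eval_stream],
        seed=seed, patch_size=patch_size)


# -- benchmark archive ------------------------------------------------------

def write_benchmark(bench: SyntheticBenchmark, directory,
                    write_frames: bool = True) -> None:
    """Persist a benchmark as a plain-file archive: ``frames/*.png``,
    ``fixations.csv``, ``labels.csv``, ``pool/<class>/*.png`` and
    ``scene.json``."""
    from PIL import Image

    root = Path(directory)
    (root / "pool").mkdir(parents=True, exist_ok=True)
    fixations = bench.task_fixations + bench.eval_fixations
    labels = bench.task_labels + bench.eval_labels
    write_fixation_table(fixations, root / "fixations.csv")
    import pandas as pd
    pd.DataFrame({"id": [f.fixation_id for f in fixations],
                  "label": labels}).to_csv(root / "labels.csv", index=False)
    if write_frames:
        fdir = root / "frames"
        fdir.mkdir(exist_ok=True)
        for i in range(bench.frames.n_frames):
            Image.fromarray(bench.frames.get_frame(i)).save(fdir / f"frame_{i}.png")
    for name in bench.schema.aoi_names:
        cdir = root / "pool" / name
        cdir.mkdir(parents=True, exist_ok=True)
        for j, patch in enumerate(bench.pool.items(name)):
            Image.fromarray(np.asarray(patch, dtype=np.uint8)).save(cdir / f"{j:03d}.png")
    doc = asdict(bench.scene)
    doc["seed"] = bench.seed
    doc["patch_size"] = bench.patch_size
    doc["bg_name"] = bench.schema.bg_name
    doc["task_phases"] = sorted({f.phase for f in bench.task_fixations if f.phase})
    (root / "scene.json").write_text(json.dumps(doc, indent=1, default=list))


def read_benchmark(directory) -> SyntheticBenchmark:
    """Load an archive written by :func:`write_benchmark` (frames are
    re-rendered lazily from the stored scene, so the archive remains valid
    with or without a ``frames/`` directory)."""
    import pandas as pd

    root = Path(directory)
    doc = json.loads((root / "scene.json").read_text())
    regions = tuple(Region(name=r["name"], rect=tuple(r["rect"]),
                           texture=Texture(**{**r["texture"],
                                              "base_color": tuple(r["texture"]["base_color"]),
                                              "pattern_color": tuple(r["texture"]["pattern_color"])}))
                    for r in doc["regions"])
    scene = SceneSpec(width=doc["width"], height=doc["height"], regions=regions,
                      background=Texture(**{**doc["background"],
                                            "base_color": tuple(doc["background"]["base_color"]),
                                            "pattern_color": tuple(doc["background"]["pattern_color"])}),
                      jitter_px=doc["jitter_px"],
                      twin_groups=tuple(tuple(g) for g in doc["twin_groups"]))
    seed = doc["seed"]
    patch_size = doc["patch_size"]
    schema = scene.schema(doc["bg_name"])

    from .io import read_fixation_table
    fixations = read_fixation_table(root / "fixations.csv")
    label_df = pd.read_csv(root / "labels.csv").set_index("id")["label"]
    task = [f for f in fixations if f.phase != "eval"]
    ev = [f for f in fixations if f.phase == "eval"]
    frames = SceneFrames(scene, max(f.frame_index for f in fixations) + 1
                         + sum(1 for _ in root.glob("pool/*/*.png")), seed=seed)
    pool = LabeledPool(schema)
    from PIL import Image
    for name in schema.aoi_names:
        for p in sorted((root / "pool" / name).glob("*.png")):
            with Image.open(p) as im:
                pool.add(name, np.asarray(im.convert("RGB")))
    pool.mark_fitted()
    return SyntheticBenchmark(
        scene=scene, schema=schema, frames=frames, pool=pool,
        task_fixations=task, task_labels=[label_df[f.fixation_id] for f in task],
        eval_fixations=ev, eval_labels=[label_df[f.fixation_id] for f in ev],
        seed=seed, patch_size=patch_size)
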
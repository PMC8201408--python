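"""Seeded synthetic elastography videos, masks and cohorts with ground truth.

Real strain-elastography recordings are not publicly deposited, so every
other module is exercised on synthetic lesions built here.  A synthetic
lesion consists of two videos (default 200 frames each, i.e. 20 s at
10 fps) whose frames are drawn from a small set of *patterns*.  A pattern
is a fixed composition of canonical elastographic colors (blue = stiff,
green/yellow = soft, red = softest) painted inside an elliptical lesion ROI
on a dark ultrasound-like background; frames of a pattern are that field
plus a per-frame global hue jitter and per-pixel channel noise.  Benign
lesions get a green-dominant composition (low stiff-area ratio, target
SAR ≈ 0.15 of the ROI), malignant lesions a blue-dominant one (SAR ≈ 0.55);
these effect sizes give strong but imperfect class separation so ROC
machinery is exercised away from AUC = 1.  A configurable share of frames
is rendered unqualified — desaturated (the elastogram overlay dropped out)
or globally dimmed (bad exposure) — to exercise the quality gates.

Because the 512-bin color histogram is invariant to spatial layout, pattern
identity in feature space is determined by the color composition; per-lesion
composition jitter keeps lesions distinguishable and per-frame noise gives
each pattern a small within-cluster radius.

An optional *test shift* interpolates a lesion's dominant composition
toward its first distractor, emulating a test-time acquisition drift that a
model trained on unshifted data has never seen: with stale cluster centers
the shifted dominant frames fall into the distractor's cluster, which is
exactly the failure mode the update-and-predict strategy repairs.

One global seed fans out to per-lesion seeds through a counter, so any
single lesion regenerates identically regardless of cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from elastoselect import quant
from elastoselect._color import rgb_from_hsv255
from elastoselect.video_io import Frame, ROIMask, VideoSequence, write_mask, write_video

CLASS_ORDER = ("blue", "green", "yellow", "red")
CLASS_HUE = {"blue": 170.0, "green": 85.0, "yellow": 43.0, "red": 8.0}
PATTERN_SAT = 220.0
PATTERN_VAL = 230.0
BACKGROUND_GRAY = 30

# Canonical pure colors for exact-arithmetic quant fixtures.
FIXTURE_RGB = {
    "blue": (0, 0, 255),
    "green": (0, 255, 0),
    "yellow": (255, 255, 0),
    "red": (255, 0, 0),
    "gray": (128, 128, 128),
}
FIXTURE_HUE = {"blue": 170.0, "green": 85.0, "yellow": 255.0 / 6, "red": 0.0, "gray": 0.0}

# Class-composition templates (blue, green, yellow, red).
BENIGN_DOMINANT = (0.15, 0.60, 0.25, 0.00)
MALIGNANT_DOMINANT = (0.55, 0.30, 0.15, 0.00)
DISTRACTOR_LIBRARY = (
    (0.05, 0.25, 0.45, 0.25),
    (0.35, 0.45, 0.15, 0.05),
    (0.70, 0.10, 0.10, 0.10),
    (0.20, 0.20, 0.40, 0.20),
    (0.45, 0.25, 0.20, 0.10),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for a synthetic cohort.

    ``dominant_fraction`` is the share of qualified frames drawn from the
    dominant pattern; ``unqualified_fraction`` the share of all frames
    failing the quality gates; ``test_shift`` the interpolation fraction of
    the dominant composition toward distractor 1 applied to lesions flagged
    as shifted (0 disables).
    """

    n_lesions: int = 24
    frames_per_video: int = 200  # 20 s at 10 fps
    videos_per_lesion: int = 2
    height: int = 128
    width: int = 128
    dominant_fraction: float = 0.6
    n_distractor_patterns: int = 3
    unqualified_fraction: float = 0.15
    noise_sd: float = 5.0
    malignant_fraction: float = 0.5
    composition_jitter: float = 0.04
    frame_hue_jitter: float = 3.0
    test_shift: float = 0.0
    fps: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dominant_fraction", "unqualified_fraction", "malignant_fraction", "test_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dominant_fraction == 0.0:
            raise ValueError("dominant_fraction must be positive")
        if self.n_lesions < 1 or self.frames_per_video < 1:
            raise ValueError("n_lesions and frames_per_video must be >= 1")
        if self.n_distractor_patterns < 0 or self.n_distractor_patterns > len(DISTRACTOR_LIBRARY):
            raise ValueError(
                f"n_distractor_patterns must lie in [0, {len(DISTRACTOR_LIBRARY)}]"
            )
        if self.dominant_fraction < 1.0 and self.n_distractor_patterns == 0:
            raise ValueError("dominant_fraction < 1 requires at least one distractor pattern")


@dataclass
class GroundTruth:
    """Generation-time truth for one lesion."""

    lesion_id: str
    label: str  # benign / malignant
    frame_labels: list[str]  # per pooled frame: dominant / distractor_<j> / unqualified
    pattern_compositions: dict[str, np.ndarray]  # pattern -> class fractions
    pattern_class_counts: dict[str, dict[str, int]]  # exact ROI pixel counts per pattern
    n_roi: int
    score: int  # synthetic expert grading score (1-5)

    def to_json(self) -> str:
        return json.dumps(
            {
                "lesion_id": self.lesion_id,
                "label": self.label,
                "score": self.score,
                "n_roi": self.n_roi,
                "frame_labels": self.frame_labels,
                "pattern_class_counts": self.pattern_class_counts,
            },
            indent=2,
            sort_keys=True,
        )


def _elliptical_mask(height: int, width: int) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    return ((yy - cy) / (0.30 * height)) ** 2 + ((xx - cx) / (0.38 * width)) ** 2 <= 1.0


def _allocate_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer allocation of ``total`` over ``fractions``."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _jitter_composition(comp: np.ndarray, rng: np.random.Generator, jitter: float) -> np.ndarray:
    out = np.clip(comp + rng.uniform(-jitter, jitter, size=len(comp)), 0.0, None)
    return out / out.sum()


def _render_pattern_frame(
    class_map: np.ndarray,
    roi: np.ndarray,
    hue_offset: float,
    rng: np.random.Generator,
    noise_sd: float,
    value_scale: float = 1.0,
    saturation: float = PATTERN_SAT,
) -> np.ndarray:
    """Paint a pattern field (class index per ROI pixel) into an RGB frame.

    The field is piecewise constant over four hues, so the per-frame hue
    jitter needs only four scalar HSV→RGB conversions.
    """
    h, w = roi.shape
    frame = np.full((h, w, 3), BACKGROUND_GRAY, dtype=float)
    hues = np.array([CLASS_HUE[c] for c in CLASS_ORDER]) + hue_offset
    colors = rgb_from_hsv255(
        np.clip(hues, 0, 255),
        np.full(len(CLASS_ORDER), saturation),
        np.full(len(CLASS_ORDER), PATTERN_VAL),
    ).astype(float)
    roi_colors = colors[class_map]
    frame[roi] = roi_colors
    frame *= value_scale
    if noise_sd > 0:
        # background speckle is achromatic (B-mode); chromatic noise only on
        # the elastogram overlay, so unsaturated pixels stay unsaturated
        frame += rng.normal(0.0, noise_sd, size=(h, w, 1))
        frame[roi] += rng.normal(0.0, noise_sd, size=(int(roi.sum()), 3))
    return np.clip(np.round(frame), 0, 255).astype(np.uint8)


def _lesion_rng(config: SynthConfig, lesion_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, lesion_index])


def lesion_label(config: SynthConfig, lesion_index: int) -> str:
    """Deterministic benign/malignant labeling: malignant lesions first."""
    n_mal = int(round(config.malignant_fraction * config.n_lesions))
    return "malignant" if lesion_index < n_mal else "benign"


def generate_lesion(
    config: SynthConfig,
    lesion_index: int,
    shifted: bool = False,
) -> tuple[list[VideoSequence], ROIMask, GroundTruth]:
    """Generate one lesion: two videos, ROI mask and ground truth.

    ``shifted`` applies ``config.test_shift`` to the dominant composition
    (interpolated toward distractor 1), emulating test-time drift.
    """
    rng = _lesion_rng(config, lesion_index)
    lesion_id = f"L{lesion_index:03d}"
    label = lesion_label(config, lesion_index)
    roi = _elliptical_mask(config.height, config.width)
    n_roi = int(roi.sum())

    dominant = np.array(MALIGNANT_DOMINANT if label == "malignant" else BENIGN_DOMINANT)
    dominant = _jitter_composition(dominant, rng, config.composition_jitter)
    idx = rng.choice(len(DISTRACTOR_LIBRARY), size=config.n_distractor_patterns, replace=False)
    distractors = [
        _jitter_composition(np.array(DISTRACTOR_LIBRARY[i]), rng, config.composition_jitter)
        for i in idx
    ]
    if shifted and config.test_shift > 0 and distractors:
        dominant = (1 - config.test_shift) * dominant + config.test_shift * distractors[0]

    compositions = {"dominant": dominant}
    compositions.update({f"distractor_{j}": c for j, c in enumerate(distractors)})

    # Pattern fields: class index per ROI pixel, allocated by exact counts
    # over a per-pattern random permutation of ROI pixels.
    class_maps: dict[str, np.ndarray] = {}
    class_counts: dict[str, dict[str, int]] = {}
    for name, comp in compositions.items():
        counts = _allocate_counts(comp, n_roi)
        cmap = np.repeat(np.arange(len(CLASS_ORDER)), counts)
        class_maps[name] = cmap[rng.permutation(n_roi)]
        class_counts[name] = {c: int(k) for c, k in zip(CLASS_ORDER, counts)}

    n_total = config.frames_per_video * config.videos_per_lesion
    n_unq = int(round(config.unqualified_fraction * n_total))
    n_qual = n_total - n_unq
    n_dom = int(round(config.dominant_fraction * n_qual))
    n_rest = n_qual - n_dom
    if n_rest > 0 and not distractors:
        raise ValueError("infeasible fractions: distractor frames requested but no distractor patterns")
    labels = ["dominant"] * n_dom
    for j, share in enumerate(_allocate_counts(np.full(len(distractors) or 1, 1.0 / max(len(distractors), 1)), n_rest)):
        if distractors:
            labels += [f"distractor_{j}"] * int(share)
    labels += ["unqualified"] * n_unq
    order = rng.permutation(n_total)
    frame_labels = [labels[i] for i in order]

    pattern_names = list(compositions)
    frames: list[Frame] = []
    for i, flabel in enumerate(frame_labels):
        hue_offset = rng.uniform(-config.frame_hue_jitter, config.frame_hue_jitter)
        if flabel == "unqualified":
            # alternate between overlay drop-out (desaturated) and under-exposure
            base = pattern_names[i % len(pattern_names)]
            if i % 2 == 0:
                px = _render_pattern_frame(
                    class_maps[base], roi, hue_offset, rng, config.noise_sd, saturation=10.0
                )
            else:
                px = _render_pattern_frame(
                    class_maps[base], roi, hue_offset, rng, config.noise_sd, value_scale=0.3
                )
        else:
            px = _render_pattern_frame(class_maps[flabel], roi, hue_offset, rng, config.noise_sd)
        frames.append(Frame(index=i, source_video="", pixels=px))

    videos = []
    for v in range(config.videos_per_lesion):
        chunk = frames[v * config.frames_per_video : (v + 1) * config.frames_per_video]
        videos.append(
            VideoSequence(
                lesion_id=lesion_id,
                frames=[
                    Frame(index=i, source_video=f"video{v + 1}", pixels=f.pixels)
                    for i, f in enumerate(chunk)
                ],
                fps=config.fps,
            )
        )

    score = int(
        rng.choice([3, 4, 5], p=[0.2, 0.4, 0.4])
        if label == "malignant"
        else rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2])
    )
    truth = GroundTruth(
        lesion_id=lesion_id,
        label=label,
        frame_labels=frame_labels,
        pattern_compositions=compositions,
        pattern_class_counts=class_counts,
        n_roi=n_roi,
        score=score,
    )
    _self_check(truth, class_maps, roi)
    return videos, ROIMask(mask=roi, lesion_id=lesion_id), truth


def _self_check(truth: GroundTruth, class_maps: dict[str, np.ndarray], roi: np.ndarray) -> None:
    """Re-measure the noiseless dominant field against the stored counts."""
    cmap = class_maps["dominant"]
    frame = _render_pattern_frame(cmap, roi, hue_offset=0.0, rng=np.random.default_rng(0), noise_sd=0.0)
    measured = quant.classify_pixels(frame, ROIMask(mask=roi, lesion_id=truth.lesion_id))
    expected = truth.pattern_class_counts["dominant"]
    for cls in CLASS_ORDER:
        if measured[cls] != expected[cls]:
            raise AssertionError(
                f"generator self-check failed for {truth.lesion_id}: "
                f"{cls} measured {measured[cls]} != planted {expected[cls]}"
            )


def stratified_split(
    labels: list[str], ratio: tuple[int, ...], names: tuple[str, ...]
) -> list[str]:
    """Assign each lesion a partition name, preserving class balance.

    Within each class, partition sizes follow ``ratio`` by largest-remainder
    allocation; assignment is by order of appearance (generation order is
    already seeded).
    """
    if len(ratio) != len(names):
        raise ValueError("ratio and names must have equal length")
    fractions = np.array(ratio, dtype=float) / sum(ratio)
    assignment = [""] * len(labels)
    for cls in sorted(set(labels)):
        members = [i for i, l in enumerate(labels) if l == cls]
        counts = _allocate_counts(fractions, len(members))
        start = 0
        for name, k in zip(names, counts):
            for i in members[start : start + k]:
                assignment[i] = name
            start += k
    return assignment


def iter_lesions(
    config: SynthConfig,
    splits: list[str] | None = None,
    shifted_splits: tuple[str, ...] = (),
):
    """Lazily generate the cohort lesion by lesion.

    Yields (lesion_index, split, videos, mask, truth).  Lesions whose split
    is in ``shifted_splits`` are generated with the test shift applied.
    """
    if splits is None:
        splits = default_splits(config)
    for i in range(config.n_lesions):
        videos, mask, truth = generate_lesion(
            config, i, shifted=splits[i] in shifted_splits
        )
        yield i, splits[i], videos, mask, truth


def default_splits(
    config: SynthConfig,
    ratio: tuple[int, ...] = (3, 1),
    names: tuple[str, ...] = ("train", "test"),
) -> list[str]:
    labels = [lesion_label(config, i) for i in range(config.n_lesions)]
    return stratified_split(labels, ratio, names)


def generate_cohort(
    config: SynthConfig,
    out_dir: str | Path,
    ratio: tuple[int, ...] = (3, 1),
    names: tuple[str, ...] = ("train", "validation"),
) -> pd.DataFrame:
    """Write a full cohort to disk in the layout ``video_io`` reads.

    Layout: ``<split>/<lesion_id>/video{1,2}/frame_*.png``, masks under
    ``masks/``, per-lesion ground truth under ``truth/`` and a
    ``metadata.csv`` with columns lesion_id, label, group, score.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    splits = default_splits(config, ratio, names)
    rows = []
    (out / "masks").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for i, split, videos, mask, truth in iter_lesions(config, splits):
        lesion_dir = out / split / truth.lesion_id
        for v, video in enumerate(videos, 1):
            write_video(video, lesion_dir / f"video{v}")
        write_mask(mask, out / "masks" / f"{truth.lesion_id}.png")
        (out / "truth" / f"{truth.lesion_id}.json").write_text(truth.to_json())
        rows.append(
            {"lesion_id": truth.lesion_id, "label": truth.label, "group": split, "score": truth.score}
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "metadata.csv", index=False)
    return df


@dataclass
class QuantFixture:
    """An image with an exactly known pixel composition and its expected metrics."""

    frame: np.ndarray
    roi: ROIMask
    expected: dict
    composition: dict


def generate_quant_fixture(composition: dict[str, int]) -> QuantFixture:
    """Build an image with exact canonical-color pixel counts.

    ``composition`` maps class names (blue, green, yellow, red, gray) to
    pixel counts; expected metrics are computed by closed-form arithmetic
    from the canonical RGB values, independently of the quant module.
    """
    unknown = set(composition) - set(FIXTURE_RGB)
    if unknown:
        raise ValueError(f"unknown fixture classes: {sorted(unknown)}")
    n = sum(composition.values())
    if n < 1:
        raise ValueError("fixture needs at least one pixel")
    pixels = np.zeros((1, n, 3), dtype=np.uint8)
    pos = 0
    for cls in sorted(composition):
        cnt = composition[cls]
        pixels[0, pos : pos + cnt] = FIXTURE_RGB[cls]
        pos += cnt
    sums = {ch: 0.0 for ch in "rgb"}
    hue_sum = 0.0
    gray_sum = 0.0
    for cls, cnt in composition.items():
        r, g, b = FIXTURE_RGB[cls]
        sums["r"] += cnt * r
        sums["g"] += cnt * g
        sums["b"] += cnt * b
        hue_sum += cnt * FIXTURE_HUE[cls]
        gray_sum += cnt * (0.299 * r + 0.587 * g + 0.114 * b)
    expected = {
        "sar": composition.get("blue", 0) / n,
        "b_g": sums["b"] / sums["g"] if sums["g"] > 0 else None,
        "b_r": sums["b"] / sums["r"] if sums["r"] > 0 else None,
        "g_r": sums["g"] / sums["r"] if sums["r"] > 0 else None,
        "mean_hue": hue_sum / n,
        "mean_gray": gray_sum / n,
        "n_roi": n,
        "counts": {
            cls: composition.get(cls, 0) for cls in ("red", "yellow", "green", "blue")
        }
        | {"unclassified": composition.get("gray", 0)},
    }
    return QuantFixture(
        frame=pixels,
        roi=ROIMask(mask=np.ones((1, n), dtype=bool), lesion_id="fixture"),
        expected=expected,
        composition=dict(composition),
    )
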
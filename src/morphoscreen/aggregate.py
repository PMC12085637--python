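"""Image-level calls, well time-courses and drug-screen summaries.

The bridge from patch predictions to biology: the classification score
vector of an image with M patches has one entry per class,

    c_i = #{j : f(p_j) = class i} / M,

where f is the network's patch prediction.  The denominator makes the
entries sum to one exactly (counts over M), and the image-level call is the
argmax of c (ties toward the lowest class index).  Calls are then arranged
into per-well hourly time-courses and reduced to per-compound screen calls
at the report hours.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .labels import CLASSES, FULL_NAMES, LABEL_TO_INDEX, PALETTE, check_label
from .model import PatchPrediction
from .patches import BrightfieldImage, PatchGridSpec


@dataclass(frozen=True)
class ScoreVector:
    """Per-image class-fraction vector c (entries are exact counts / M)."""

    image_id: str
    class_counts: tuple[int, ...]  # one count per class, in CLASSES order

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(CLASSES):
            raise DataError("score vector needs one count per class")
        if any(c < 0 for c in self.class_counts) or self.m < 1:
            raise DataError("score vector requires >= 1 patch and counts >= 0")

    @property
    def m(self) -> int:
        """Number of patches of the image."""
        return sum(self.class_counts)

    @property
    def fractions(self) -> tuple[Fraction, ...]:
        """Exact rational entries; they sum to 1 by construction."""
        return tuple(Fraction(c, self.m) for c in self.class_counts)

    @property
    def values(self) -> np.ndarray:
        return np.array(self.class_counts, dtype=np.float64) / self.m


def score_vector(
    predictions: Sequence[PatchPrediction] | Sequence[str],
    image_id: str | None = None,
) -> ScoreVector:
    """Tally predicted patch labels of one image into a score vector."""
    if len(predictions) == 0:
        raise DataError("cannot build a score vector from zero predictions")
    if isinstance(predictions[0], PatchPrediction):
        parents = {p.patch_id.rsplit(":", 1)[0] for p in predictions}
        if len(parents) > 1:
            raise DataError(f"predictions span multiple images: {sorted(parents)}")
        if image_id is None:
            image_id = parents.pop()
        labels = [p.label for p in predictions]
    else:
        labels = [check_label(l) for l in predictions]
        image_id = image_id or "image"
    counts = [0] * len(CLASSES)
    for lab in labels:
        counts[LABEL_TO_INDEX[lab]] += 1
    return ScoreVector(image_id=image_id, class_counts=tuple(counts))


def call_image(score: ScoreVector) -> str:
    """Majority-vote image call: argmax of c, ties to the lowest class index."""
    return CLASSES[int(np.argmax(score.class_counts))]


@dataclass
class ImageCall:
    """An image-level classification with its supporting score vector."""

    image_id: str
    score: ScoreVector
    label: str = ""
    well_id: str | None = None
    hour: int | None = None

    def __post_init__(self) -> None:
        if not self.label:
            self.label = call_image(self.score)
        check_label(self.label)


# ---------------------------------------------------------------------------
# time-courses


@dataclass
class WellTimecourse:
    """Hour-ordered image calls of one well; missing hours are None."""

    well_id: str
    hours: tuple[int, ...]
    labels: tuple[str | None, ...]

    def __len__(self) -> int:
        return len(self.hours)

    @property
    def complete(self) -> bool:
        return all(l is not None for l in self.labels)


def assemble_timecourse(
    calls: Sequence[ImageCall], hours: Sequence[int] | None = None
) -> WellTimecourse:
    """Order one well's calls by acquisition hour.

    ``hours`` fixes the reported hour axis (gaps marked missing); when
    omitted, every hour from the earliest to the latest call is reported.
    """
    if len(calls) == 0:
        return WellTimecourse(well_id="", hours=(), labels=())
    wells = {c.well_id for c in calls}
    if len(wells) > 1:
        raise DataError(f"time-course mixes wells: {sorted(map(str, wells))}")
    by_hour: dict[int, str] = {}
    for c in calls:
        if c.hour is None:
            raise DataError(f"call for image {c.image_id!r} has no hour")
        if c.hour in by_hour:
            raise DataError(f"duplicate call for well {c.well_id!r} at hour {c.hour}")
        by_hour[c.hour] = c.label
    if hours is None:
        hours = range(min(by_hour), max(by_hour) + 1)
    hours = tuple(int(h) for h in hours)
    return WellTimecourse(
        well_id=wells.pop() or "",
        hours=hours,
        labels=tuple(by_hour.get(h) for h in hours),
    )


# ---------------------------------------------------------------------------
# plate maps and screen summaries

_ROWS_384 = string.ascii_uppercase[:16]  # A..P


def well_names_384() -> list[str]:
    return [f"{r}{c}" for r in _ROWS_384 for c in range(1, 25)]


def _check_well_384(well: str) -> str:
    row, col = well[:1], well[1:]
    if row not in _ROWS_384 or not col.isdigit() or not 1 <= int(col) <= 24:
        raise DataError(f"{well!r} is not a valid 384-well coordinate (A1..P24)")
    return well


@dataclass
class PlateMap:
    """384-well plate layout: well -> compound, concentration, role."""

    plate_id: str
    wells: pd.DataFrame  # columns: well, compound, concentration_nM, role

    def __post_init__(self) -> None:
        required = {"well", "compound", "concentration_nM", "role"}
        if not required.issubset(self.wells.columns):
            raise DataError(f"plate map must have columns {sorted(required)}")
        for row in self.wells.itertuples(index=False):
            _check_well_384(row.well)
            if row.role not in ("treatment", "vehicle"):
                raise DataError(f"unknown well role {row.role!r}")
            if row.role == "treatment" and not row.concentration_nM > 0:
                raise DataError(
                    f"treatment well {row.well} needs a positive concentration"
                )

    def lookup(self, well: str) -> tuple[str, float, str]:
        hit = self.wells[self.wells["well"] == well]
        if hit.empty:
            raise DataError(f"well {well!r} not present in plate map {self.plate_id!r}")
        row = hit.iloc[0]
        return str(row["compound"]), float(row["concentration_nM"]), str(row["role"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateMap":
        df = pd.read_csv(path)
        plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df.columns else Path(path).stem
        return cls(plate_id=plate_id, wells=df.drop(columns=["plate_id"], errors="ignore"))

    def to_csv(self, path: str | Path) -> None:
        out = self.wells.copy()
        out.insert(0, "plate_id", self.plate_id)
        out.to_csv(path, index=False)

    @classmethod
    def randomized(
        cls,
        compounds: Sequence[str],
        concentrations_nM: Sequence[float] = (5.0, 100.0, 2000.0, 25000.0),
        n_vehicle: int = 16,
        plate_id: str = "plate1",
        seed: int = 0,
    ) -> "PlateMap":
        """Assign compound x concentration combinations to random well positions.

        Vehicle (DMSO) wells are interspersed; remaining wells stay empty.
        Mirrors a dispensing robot's randomized layout.
        """
        combos = [(c, conc) for c in compounds for conc in concentrations_nM]
        need = len(combos) + n_vehicle
        names = well_names_384()
        if need > len(names):
            raise DataError(f"{need} wells requested but a 384-well plate has 384")
        rng = np.random.default_rng(seed)
        chosen = [names[i] for i in rng.permutation(len(names))[:need]]
        rows = [
            {"well": w, "compound": comp, "concentration_nM": conc, "role": "treatment"}
            for w, (comp, conc) in zip(chosen[: len(combos)], combos)
        ]
        rows += [
            {"well": w, "compound": "DMSO", "concentration_nM": 0.0, "role": "vehicle"}
            for w in chosen[len(combos) :]
        ]
        return cls(plate_id=plate_id, wells=pd.DataFrame(rows))


@dataclass
class ScreenCall:
    """One screen-report record (per concentration, or a per-compound headline)."""

    compound: str
    concentration_nM: float | None  # None for headline records
    hour: int
    label: str
    headline: bool = False
    scores: list[ScoreVector] = field(default_factory=list)

    @property
    def classified_cell_death(self) -> str:
        return FULL_NAMES[self.label]


def summarize_screen(
    calls: Sequence[ImageCall],
    plate_map: PlateMap,
    report_hours: tuple[int, ...] = (24, 48),
) -> list[ScreenCall]:
    """Reduce well calls to per-compound screen records at the report hours.

    Emits one record per (compound, concentration, report hour) carrying
    that well's image-level call, plus one *headline* record per compound
    and hour: the modal call across its concentrations, ties broken toward
    the call of the highest concentration.  Vehicle wells called 'hea'
    appear as Healthy controls.
    """
    annotated = []
    for c in calls:
        if c.well_id is None:
            raise DataError(f"call for image {c.image_id!r} has no well id")
        compound, conc, role = plate_map.lookup(c.well_id)
        annotated.append((compound, conc, role, c))

    out: list[ScreenCall] = []
    compounds = sorted({a[0] for a in annotated})
    for hour in report_hours:
        for compound in compounds:
            recs = sorted(
                (
                    (conc, c)
                    for comp, conc, _, c in annotated
                    if comp == compound and c.hour == hour
                ),
                key=lambda t: t[0],
            )
            if not recs:
                continue
            for conc, c in recs:
                out.append(
                    ScreenCall(compound, conc, hour, c.label, scores=[c.score])
                )
            # headline: modal call, tie -> call of the highest concentration
            tally: dict[str, int] = {}
            for _, c in recs:
                tally[c.label] = tally.get(c.label, 0) + 1
            top = max(tally.values())
            tied = {lab for lab, n in tally.items() if n == top}
            headline_label = next(
                c.label for conc, c in reversed(recs) if c.label in tied
            )
            out.append(
                ScreenCall(
                    compound,
                    None,
                    hour,
                    headline_label,
                    headline=True,
                    scores=[c.score for _, c in recs],
                )
            )
    return out


def screen_report_frame(screen_calls: Sequence[ScreenCall]) -> pd.DataFrame:
    """Tabular screen report (compound, classified cell death, ...)."""
    return pd.DataFrame(
        [
            {
                "compound": s.compound,
                "classified_cell_death": s.classified_cell_death,
                "concentration_nM": s.concentration_nM,
                "hour": s.hour,
                "headline": s.headline,
            }
            for s in screen_calls
        ]
    )


# ---------------------------------------------------------------------------
# overlays


def render_overlay(
    image: BrightfieldImage,
    predictions: Sequence[PatchPrediction],
    grid: PatchGridSpec,
    palette: Mapping[str, tuple[float, float, float]] = PALETTE,
    alpha: float = 0.45,
) -> np.ndarray:
    """Tint each patch region with its predicted class color over the frame.

    Returns an (H, W, 3) float RGB array in [0, 1].
    """
    h, w = image.shape
    grid.validate_for(h, w)
    by_pos: dict[tuple[int, int], str] = {}
    for p in predictions:
        parent, pos = p.patch_id.rsplit(":", 1)
        if parent != image.image_id:
            raise DataError(
                f"prediction {p.patch_id!r} does not belong to image {image.image_id!r}"
            )
        r, c = pos[1:].split("c")
        by_pos[(int(r), int(c))] = p.label
    needed = {(r, c) for r in range(grid.rows) for c in range(grid.cols)}
    if set(by_pos) != needed:
        raise DataError("predictions do not cover the patch grid exactly")
    rgb = np.repeat(image.pixels[:, :, None], 3, axis=2).astype(np.float32)
    ps = grid.patch_size
    for (r, c), label in by_pos.items():
        ro, co = grid.row_offsets[r], grid.col_offsets[c]
        color = np.array(palette[label], dtype=np.float32)
        region = rgb[ro : ro + ps, co : co + ps]
        rgb[ro : ro + ps, co : co + ps] = (1 - alpha) * region + alpha * color
    return np.clip(rgb, 0.0, 1.0)


def write_overlay_png(rgb: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.round(rgb * 255).astype(np.uint8))
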
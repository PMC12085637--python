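"""Score vectors, image calls, time-courses, screen summaries, overlays."""

from __future__ import annotations

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

import morphoscreen as ms
from morphoscreen.errors import DataError
from morphoscreen.model import PatchPrediction


def _onehot_pred(pid, label):
    probs = np.full(5, 0.01)
    probs[ms.CLASSES.index(label)] = 0.96
    return PatchPrediction(pid, probs)


# -- score vector ------------------------------------------------------------


def test_score_vector_degenerate_and_even_split():
    sv = ms.score_vector(["fer"] * 16)
    assert tuple(sv.values) == (0, 0, 1, 0, 0)
    sv = ms.score_vector(["apo"] * 8 + ["hea"] * 8)
    assert tuple(sv.values) == (0.5, 0, 0, 0.5, 0)


def test_score_vector_sums_to_one_exactly(rng):
    for _ in range(50):
        labels = list(rng.choice(ms.CLASSES, size=int(rng.integers(1, 353))))
        sv = ms.score_vector(labels)
        assert sum(sv.fractions) == Fraction(1)  # exact rational identity
        tally = Counter(labels)  # independent hash-map counting oracle
        for lab, frac in zip(ms.CLASSES, sv.fractions):
            assert frac == Fraction(tally.get(lab, 0), len(labels))


def test_score_vector_from_predictions_checks_single_image():
    preds = [_onehot_pred(f"img1:r0c{c}", "aut") for c in range(4)]
    sv = ms.score_vector(preds)
    assert sv.image_id == "img1"
    assert tuple(sv.values) == (0, 1, 0, 0, 0)
    mixed = preds + [_onehot_pred("img2:r0c0", "aut")]
    with pytest.raises(DataError):
        ms.score_vector(mixed)
    with pytest.raises(DataError):
        ms.score_vector([])


# -- image calls -------------------------------------------------------------


def test_call_image_argmax_and_tie_rule():
    assert ms.call_image(ms.ScoreVector("x", (0, 0, 16, 0, 0))) == "fer"
    assert ms.call_image(ms.ScoreVector("x", (8, 0, 0, 8, 0))) == "apo"  # tie rule


def test_call_matches_linear_scan_oracle(rng):
    for _ in range(1000):
        counts = tuple(int(c) for c in rng.integers(0, 20, size=5))
        if sum(counts) == 0:
            continue
        sv = ms.ScoreVector("x", counts)
        best, best_val = 0, -1
        for i, v in enumerate(counts):  # brute-force max scan, first winner
            if v > best_val:
                best, best_val = i, v
        assert ms.call_image(sv) == ms.CLASSES[best]


def test_call_permutation_invariant(rng):
    labels = list(rng.choice(ms.CLASSES, size=48))
    call1 = ms.call_image(ms.score_vector(labels))
    perm = list(rng.permutation(labels))
    call2 = ms.call_image(ms.score_vector(perm))
    assert call1 == call2


# -- time-courses ------------------------------------------------------------


def _call(well, hour, label):
    return ms.ImageCall(
        image_id=f"{well}_h{hour}",
        score=ms.score_vector([label] * 4),
        well_id=well,
        hour=hour,
    )


def test_hourly_timecourse_has_24_entries():
    calls = [_call("B2", h, "fer") for h in range(1, 25)]
    tc = ms.assemble_timecourse(calls)
    assert len(tc) == 24
    assert tc.complete
    assert tc.labels == ("fer",) * 24


def test_timecourse_sorting_matches_sorted_input(rng):
    hours = list(range(1, 25))
    calls = [_call("C3", h, ms.CLASSES[h % 5]) for h in hours]
    shuffled = [calls[i] for i in rng.permutation(len(calls))]
    assert ms.assemble_timecourse(shuffled) == ms.assemble_timecourse(calls)


def test_timecourse_gaps_marked_missing_and_duplicates_rejected():
    calls = [_call("D4", 1, "hea"), _call("D4", 3, "apo")]
    tc = ms.assemble_timecourse(calls)
    assert tc.hours == (1, 2, 3)
    assert tc.labels == ("hea", None, "apo")
    assert not tc.complete
    with pytest.raises(DataError):
        ms.assemble_timecourse(calls + [_call("D4", 3, "nec")])
    with pytest.raises(DataError):
        ms.assemble_timecourse([_call("D4", 1, "hea"), _call("E4", 2, "hea")])
    assert len(ms.assemble_timecourse([])) == 0


# -- plate maps --------------------------------------------------------------


def test_plate_map_validates_wells_and_roles():
    import pandas as pd

    good = pd.DataFrame(
        [
            {"well": "A1", "compound": "drugA", "concentration_nM": 100.0, "role": "treatment"},
            {"well": "P24", "compound": "DMSO", "concentration_nM": 0.0, "role": "vehicle"},
        ]
    )
    pm = ms.PlateMap("p", good)
    assert pm.lookup("A1") == ("drugA", 100.0, "treatment")
    for bad_row in (
        {"well": "Q1", "compound": "x", "concentration_nM": 1.0, "role": "treatment"},
        {"well": "A25", "compound": "x", "concentration_nM": 1.0, "role": "treatment"},
        {"well": "A1", "compound": "x", "concentration_nM": 0.0, "role": "treatment"},
        {"well": "A1", "compound": "x", "concentration_nM": 1.0, "role": "mystery"},
    ):
        with pytest.raises(DataError):
            ms.PlateMap("p", pd.DataFrame([bad_row]))
    with pytest.raises(DataError):
        pm.lookup("B9")


def test_randomized_plate_layout(tmp_path):
    pm = ms.PlateMap.randomized(["a", "b", "c"], (5.0, 50.0), n_vehicle=4, seed=3)
    assert len(pm.wells) == 3 * 2 + 4
    assert pm.wells["well"].is_unique
    assert (pm.wells.loc[pm.wells["role"] == "vehicle", "compound"] == "DMSO").all()
    pm.to_csv(tmp_path / "pm.csv")
    back = ms.PlateMap.from_csv(tmp_path / "pm.csv")
    assert back.wells["well"].tolist() == pm.wells["well"].tolist()


# -- screen summaries --------------------------------------------------------


def _screen_setup():
    import pandas as pd

    rows = [
        {"well": "A1", "compound": "drugX", "concentration_nM": 5.0, "role": "treatment"},
        {"well": "A2", "compound": "drugX", "concentration_nM": 100.0, "role": "treatment"},
        {"well": "A3", "compound": "drugX", "concentration_nM": 2000.0, "role": "treatment"},
        {"well": "B1", "compound": "DMSO", "concentration_nM": 0.0, "role": "vehicle"},
    ]
    return ms.PlateMap("p1", pd.DataFrame(rows))


def test_modal_headline_call_matches_tally_oracle():
    pm = _screen_setup()
    calls = [
        _call("A1", 24, "fer"),
        _call("A2", 24, "fer"),
        _call("A3", 24, "apo"),
        _call("B1", 24, "hea"),
    ]
    screen = ms.summarize_screen(calls, pm, report_hours=(24,))
    headline = {s.compound: s for s in screen if s.headline}
    assert headline["drugX"].label == "fer"  # modal across concentrations
    assert headline["DMSO"].label == "hea"
    assert headline["DMSO"].classified_cell_death == "Healthy"
    # one record per (compound, concentration, hour) + one headline each
    assert len(screen) == 4 + 2


def test_headline_tie_breaks_toward_highest_concentration():
    pm = _screen_setup()
    calls = [
        _call("A1", 24, "fer"),
        _call("A2", 24, "apo"),
        _call("A3", 24, "apo"),
        _call("B1", 24, "hea"),
    ]
    # 2 apo vs 1 fer: modal apo regardless of tie rule
    screen = ms.summarize_screen(calls, pm, report_hours=(24,))
    assert next(s for s in screen if s.headline and s.compound == "drugX").label == "apo"
    # now a genuine 1-1-1 pattern cannot occur with 3 wells of 2 labels; use tie
    calls = [
        _call("A1", 24, "fer"),
        _call("A2", 24, "fer"),
        _call("A3", 24, "apo"),
        _call("B1", 24, "hea"),
    ]
    calls2 = [
        _call("A1", 24, "apo"),
        _call("A2", 24, "apo"),
        _call("A3", 24, "fer"),
        _call("B1", 24, "hea"),
    ]
    s1 = ms.summarize_screen(calls, pm, report_hours=(24,))
    s2 = ms.summarize_screen(calls2, pm, report_hours=(24,))
    assert next(s for s in s1 if s.headline and s.compound == "drugX").label == "fer"
    assert next(s for s in s2 if s.headline and s.compound == "drugX").label == "apo"


def test_two_way_tie_uses_highest_concentration_call():
    import pandas as pd

    rows = [
        {"well": "A1", "compound": "d", "concentration_nM": 5.0, "role": "treatment"},
        {"well": "A2", "compound": "d", "concentration_nM": 100.0, "role": "treatment"},
    ]
    pm = ms.PlateMap("p", pd.DataFrame(rows))
    calls = [_call("A1", 24, "nec"), _call("A2", 24, "fer")]
    screen = ms.summarize_screen(calls, pm, report_hours=(24,))
    assert next(s for s in screen if s.headline).label == "fer"


def test_unmapped_well_and_empty_screen():
    pm = _screen_setup()
    with pytest.raises(DataError):
        ms.summarize_screen([_call("H12", 24, "fer")], pm)
    assert ms.summarize_screen([], pm) == []


def test_report_frame_schema():
    pm = _screen_setup()
    calls = [_call("A1", 24, "fer"), _call("B1", 24, "hea")]
    df = ms.screen_report_frame(ms.summarize_screen(calls, pm, report_hours=(24,)))
    assert list(df.columns) == [
        "compound",
        "classified_cell_death",
        "concentration_nM",
        "hour",
        "headline",
    ]
    dmso = df[(df["compound"] == "DMSO") & df["headline"]]
    assert dmso["classified_cell_death"].tolist() == ["Healthy"]


# -- overlays ----------------------------------------------------------------


def test_overlay_tints_patches_with_palette_colors(rng):
    pixels = rng.random((448, 448)).astype(np.float32)
    img = ms.BrightfieldImage("ov", pixels)
    grid = ms.PatchGridSpec.tiling(448, 448)
    labels = ["apo", "fer", "hea", "nec"]
    preds = [
        _onehot_pred(f"ov:r{r}c{c}", labels[r * 2 + c])
        for r in range(2)
        for c in range(2)
    ]
    alpha = 0.45
    rgb = ms.render_overlay(img, preds, grid, alpha=alpha)
    assert rgb.shape == (448, 448, 3)
    for k, (r, c) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        cy, cx = r * 224 + 112, c * 224 + 112
        expected = (1 - alpha) * pixels[cy, cx] + alpha * np.array(ms.PALETTE[labels[k]])
        assert np.allclose(rgb[cy, cx], expected, atol=1e-6)


def test_overlay_single_patch_uniform_tint():
    img = ms.BrightfieldImage("u", np.full((224, 224), 0.5, np.float32))
    grid = ms.PatchGridSpec.tiling(224, 224)
    rgb = ms.render_overlay(img, [_onehot_pred("u:r0c0", "nec")], grid)
    assert np.allclose(rgb, rgb[0, 0])  # one uniform color everywhere


def test_overlay_rejects_grid_mismatch(rng):
    img = ms.BrightfieldImage("m", rng.random((448, 448)).astype(np.float32))
    grid = ms.PatchGridSpec.tiling(448, 448)
    with pytest.raises(DataError):
        ms.render_overlay(img, [_onehot_pred("m:r0c0", "apo")], grid)
    with pytest.raises(DataError):
        ms.render_overlay(
            img, [_onehot_pred(f"other:r{r}c{c}", "apo") for r in range(2) for c in range(2)], grid
        )
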
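"""Epicenter detection, scatter score and the chronicity association."""

import numpy as np
import pandas as pd
import pytest

from painsgrid import (
    BodyAtlas,
    DegenerateInputError,
    EmptyCohortError,
    PainMap,
    build_default_atlas,
    chronicity_association,
    find_epicenter,
    grid_distances,
    scatter_score,
    scatter_scores_at_baseline,
    scope_cells,
)

ATLAS = build_default_atlas()
HEAD = sorted(scope_cells(ATLAS, "head"))


def _maps(mark_sets):
    return [
        PainMap(f"p{i}", 0, dict(marks)) for i, marks in enumerate(mark_sets)
    ]


class TestFindEpicenter:
    def test_modal_cell_by_brute_force(self):
        rng = np.random.default_rng(5)
        cohort = []
        for i in range(30):
            cells = rng.choice(HEAD[:50], size=8, replace=False)
            cohort.append(
                PainMap(f"p{i}", 0, {int(c): int(rng.integers(1, 4)) for c in cells})
            )
        counts = {}
        for pm in cohort:
            for c in pm.marks:
                counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        result = find_epicenter(cohort, ATLAS, "head")
        assert result.frequency == best
        assert counts[result.epicenter_cell] == best

    def test_single_patient_single_cell(self):
        result = find_epicenter([PainMap("p1", 0, {HEAD[4]: 2})], ATLAS, "head")
        assert result.epicenter_cell == HEAD[4]
        assert result.frequency == 1

    def test_frequency_tie_broken_by_intensity_sum(self):
        a, b = HEAD[5], HEAD[9]
        cohort = _maps([{a: 3, b: 1}, {a: 3, b: 1}])
        assert find_epicenter(cohort, ATLAS, "head").epicenter_cell == a

    def test_full_tie_broken_by_smaller_cell_id(self):
        a, b = HEAD[5], HEAD[9]
        cohort = _maps([{a: 2, b: 2}])
        assert find_epicenter(cohort, ATLAS, "head").epicenter_cell == min(a, b)

    def test_no_painful_cells_raises(self):
        with pytest.raises(EmptyCohortError):
            find_epicenter(_maps([{}]), ATLAS, "head")


class TestScatterScore:
    def test_zero_when_all_pain_on_epicenter(self):
        assert scatter_score(PainMap("p", 0, {HEAD[0]: 3}), HEAD[0], ATLAS).score == 0

    def test_single_cell_equals_its_distance(self):
        epi = HEAD[0]
        d = grid_distances(ATLAS, epi)
        target = next(c for c in HEAD if d.loc[c] == 5.0)
        for intensity in (1, 3):
            s = scatter_score(PainMap("p", 0, {target: intensity}), epi, ATLAS)
            assert s.score == pytest.approx(5.0)

    def test_three_cell_weighted_mean(self):
        epi = HEAD[0]
        d = grid_distances(ATLAS, epi)
        cells = HEAD[1:4]
        marks = {cells[0]: 1, cells[1]: 2, cells[2]: 3}
        expect = sum(w * d.loc[c] for c, w in marks.items()) / 6
        s = scatter_score(PainMap("p", 0, marks), epi, ATLAS)
        assert s.score == pytest.approx(expect)

    def test_uniform_intensity_rescaling_invariance(self):
        epi = HEAD[0]
        cells = HEAD[2:7]
        scores = [
            scatter_score(PainMap("p", 0, {c: k for c in cells}), epi, ATLAS).score
            for k in (1, 2, 3)
        ]
        assert scores[0] == pytest.approx(scores[1]) == pytest.approx(scores[2])

    def test_translation_invariance(self):
        """Shifting a segment chart by a constant leaves scores unchanged."""
        shifted_cells = ATLAS.cells.copy()
        head_mask = shifted_cells["segment"] == "head"
        shifted_cells.loc[head_mask, "row"] += 11
        shifted_cells.loc[head_mask, "col"] += 4
        shifted = BodyAtlas(cells=shifted_cells, regions=ATLAS.regions.copy())
        epi = HEAD[0]
        pm = PainMap("p", 0, {HEAD[3]: 2, HEAD[10]: 3, HEAD[40]: 1})
        assert scatter_score(pm, epi, ATLAS).score == pytest.approx(
            scatter_score(pm, epi, shifted).score
        )

    def test_cross_segment_distance_uses_chart_penalty(self):
        epi = HEAD[0]
        foot = sorted(scope_cells(ATLAS, "foot"))[0]
        penalty = max(ATLAS.segment_diagonal("head"), ATLAS.segment_diagonal("foot"))
        s = scatter_score(PainMap("p", 0, {foot: 2}), epi, ATLAS)
        assert s.score == pytest.approx(penalty)


class TestChronicityAssociation:
    def test_perfectly_proportional_scores(self):
        scatter = pd.DataFrame(
            {"patient_id": ["a", "b", "c", "d"], "scatter": [1.0, 2.0, 3.0, 4.0]}
        )
        meta = pd.DataFrame(
            {"patient_id": ["a", "b", "c", "d"],
             "arm": ["active"] * 4,
             "pain_duration_years": [2.0, 4.0, 6.0, 8.0]}
        )
        out = chronicity_association(scatter, meta)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(0.5)

    def test_matches_covariance_formula_on_toy_table(self):
        dur = np.array([1.0, 3.0, 4.0, 7.0, 9.0])
        sct = np.array([2.0, 2.5, 4.0, 3.5, 6.0])
        scatter = pd.DataFrame(
            {"patient_id": list("abcde"), "scatter": sct}
        )
        meta = pd.DataFrame(
            {"patient_id": list("abcde"), "arm": ["sham"] * 5,
             "pain_duration_years": dur}
        )
        r_oracle = float(
            ((dur - dur.mean()) * (sct - sct.mean())).sum()
            / np.sqrt(((dur - dur.mean()) ** 2).sum() * ((sct - sct.mean()) ** 2).sum())
        )
        assert chronicity_association(scatter, meta)["r"] == pytest.approx(r_oracle)

    def test_permuted_durations_uncorrelated(self):
        rng = np.random.default_rng(0)
        n = 400
        scatter = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(n)],
             "scatter": rng.normal(4, 1, n)}
        )
        meta = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(n)], "arm": ["sham"] * n,
             "pain_duration_years": rng.uniform(1, 10, n)}
        )
        assert abs(chronicity_association(scatter, meta)["r"]) < 0.12

    def test_degenerate_inputs_rejected(self):
        flat = pd.DataFrame(
            {"patient_id": list("abc"), "scatter": [2.0, 2.0, 2.0]}
        )
        meta = pd.DataFrame(
            {"patient_id": list("abc"), "arm": ["sham"] * 3,
             "pain_duration_years": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(DegenerateInputError):
            chronicity_association(flat, meta)
        with pytest.raises(DegenerateInputError):
            chronicity_association(flat.iloc[:2], meta.iloc[:2])

    def test_baseline_pipeline_on_cohort(self, atlas, default_cohort):
        scatter = scatter_scores_at_baseline(default_cohort.painmaps, atlas,
                                             "head_neck")
        assert len(scatter) == 24
        assert (scatter["scatter"] >= 0).all()
        epi = scatter.attrs["epicenter_cell"]
        assert epi in scope_cells(atlas, "head_neck")
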
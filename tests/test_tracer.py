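"""Isotopologue pair matching and enrichment verdicts on planted truth."""

import numpy as np
import pandas as pd
import pytest

from befa.chem_mass import deuterium_shift
from befa.feature_io import FeatureTable
from befa.routes import standard_predictions
from befa.simulate import generate_differential_table, generate_tracer_table
from befa.tracer import (
    TracerDesign,
    TracerPair,
    annotate_predictions,
    find_label_pairs,
    pairs_to_frame,
    score_enrichment,
)

DESIGN = TracerDesign(labeled_group="labeled", control_group="control")


def tracer_base(seed: int, **kw):
    kw.setdefault("group_names", ("control", "labeled"))
    kw.setdefault("n_differential", 0)
    kw.setdefault("fold_change", 1.0)
    kw.setdefault("include_reference", False)
    return generate_differential_table(seed=seed, **kw)


def manual_table(rows, groups=("labeled", "control")):
    """rows: feature_id -> (mz, rt, labeled_mean, control_mean)."""
    ids = list(rows)
    f = pd.DataFrame(
        {"mz": [rows[i][0] for i in ids], "rt": [rows[i][1] for i in ids], "ion_mode": "neg"},
        index=pd.Index(ids, name="feature_id"),
    )
    manifest = pd.DataFrame(
        {"group": ["labeled", "labeled", "control", "control"]},
        index=pd.Index(["L1", "L2", "C1", "C2"], name="sample_id"),
    )
    x = pd.DataFrame(
        {
            "L1": [rows[i][2] for i in ids], "L2": [rows[i][2] for i in ids],
            "C1": [rows[i][3] for i in ids], "C2": [rows[i][3] for i in ids],
        },
        index=f.index,
    )
    return FeatureTable(f, x, manifest)


class TestFindLabelPairs:
    def test_planted_d3_pair_recovered(self):
        table = manual_table({
            "u": (183.1391, 300.0, 50_000, 50_000),
            "l": (183.1391 + deuterium_shift(3), 298.0, 40_000, 100),
        })
        pairs = find_label_pairs(table, DESIGN)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.unlabeled_id, p.labeled_id, p.n_deuterium) == ("u", "l", 3)
        assert abs(p.mass_error_ppm) < 1e-6
        assert p.delta_rt == -2.0

    def test_non_integer_shift_unmatched(self):
        table = manual_table({
            "u": (183.1391, 300.0, 50_000, 50_000),
            "x": (183.1391 + 3.50, 300.0, 40_000, 100),
        })
        assert find_label_pairs(table, TracerDesign("labeled", "control", n_range=(1, 3))) == []

    def test_coelution_window_rejects_distant_rt(self):
        table = manual_table({
            "u": (183.1391, 300.0, 50_000, 50_000),
            "l": (183.1391 + deuterium_shift(3), 360.0, 40_000, 100),
        })
        assert find_label_pairs(table, DESIGN) == []

    def test_recall_precision_one_on_noiseless_planted_pairs(self):
        base, base_truth = tracer_base(seed=101, n_features=150)
        table, truth = generate_tracer_table(
            base, labeled_fraction=0.2, n_d_values=(3, 11), ppm_jitter=0.0,
            rt_shift=-2.0, seed=7, base_truth=base_truth,
        )
        pairs = find_label_pairs(table, DESIGN)
        found = {(p.unlabeled_id, p.labeled_id, p.n_deuterium) for p in pairs}
        planted = {(r.parent_id, r.partner_id, r.n_d) for r in truth.itertuples()}
        assert planted <= found  # recall 1.0
        assert found <= planted  # precision 1.0

    def test_matching_invariant_to_order_and_intensity_scale(self):
        base, base_truth = tracer_base(seed=103, n_features=80)
        table, _ = generate_tracer_table(base, labeled_fraction=0.25, seed=9,
                                         base_truth=base_truth)
        pairs = find_label_pairs(table, DESIGN)
        key = {(p.unlabeled_id, p.labeled_id, p.n_deuterium) for p in pairs}

        rng = np.random.default_rng(0)
        shuffled = table.subset(rng.permutation(table.features.index))
        scaled = FeatureTable(shuffled.features, shuffled.intensities * 7.3,
                              shuffled.manifest)
        pairs2 = find_label_pairs(scaled, DESIGN)
        assert {(p.unlabeled_id, p.labeled_id, p.n_deuterium) for p in pairs2} == key

    def test_high_jitter_degrades_recall(self):
        base, base_truth = tracer_base(seed=105, n_features=200)
        table, truth = generate_tracer_table(
            base, labeled_fraction=0.3, ppm_jitter=10.0, seed=11, base_truth=base_truth,
        )
        pairs = find_label_pairs(table, DESIGN)
        found = {(p.unlabeled_id, p.labeled_id) for p in pairs}
        planted = {(r.parent_id, r.partner_id) for r in truth.itertuples()}
        recall = len(found & planted) / len(planted)
        assert recall < 1.0


class TestEnrichment:
    def _pair(self):
        return TracerPair("u", "l", 3, deuterium_shift(3), deuterium_shift(3), 0.0, -2.0)

    def test_absent_from_control_is_enriched(self):
        table = manual_table({"u": (183.1391, 300, 50_000, 50_000),
                              "l": (183.1391 + deuterium_shift(3), 298, 50_000, 0)})
        assert score_enrichment(self._pair(), table, DESIGN) == "enriched"

    def test_equal_in_both_groups_not_enriched(self):
        table = manual_table({"u": (183.1391, 300, 50_000, 50_000),
                              "l": (183.1391 + deuterium_shift(3), 298, 50_000, 50_000)})
        assert score_enrichment(self._pair(), table, DESIGN) == "not-enriched"

    def test_twofold_over_control_is_ambiguous(self):
        table = manual_table({"u": (183.1391, 300, 50_000, 50_000),
                              "l": (183.1391 + deuterium_shift(3), 298, 40_000, 20_000)})
        assert score_enrichment(self._pair(), table, DESIGN) == "ambiguous"

    def test_below_detection_floor_not_enriched(self):
        table = manual_table({"u": (183.1391, 300, 50_000, 50_000),
                              "l": (183.1391 + deuterium_shift(3), 298, 5_000, 0)})
        assert score_enrichment(self._pair(), table, DESIGN) == "not-enriched"

    def test_null_condition_yields_zero_enriched(self):
        # labeled group is statistically a copy of control: specificity check
        enriched = 0
        for seed in range(20):
            base, base_truth = tracer_base(seed=seed, n_features=100)
            table, _ = generate_tracer_table(
                base, labeled_fraction=0.0, seed=seed + 1000, base_truth=base_truth,
            )
            pairs = find_label_pairs(table, DESIGN)
            design = DESIGN
            enriched += sum(score_enrichment(p, table, design) == "enriched" for p in pairs)
        assert enriched == 0


class TestAnnotation:
    def test_d11_partner_matches_predicted_metabolite(self):
        preds = standard_predictions("d13_cis")
        d11 = next(p for p in preds if p.n_d == 11)
        table = manual_table({
            "u": (215.1289, 400, 50_000, 50_000),
            "l": (215.1289 + deuterium_shift(11), 398, 40_000, 100),
        })
        pairs = find_label_pairs(table, DESIGN)
        annotated = annotate_predictions(pairs, preds, table)
        assert annotated[0].n_deuterium == 11
        assert d11.name in annotated[0].predicted_matches

    def test_integer_mismatch_untagged(self):
        preds = [p for p in standard_predictions("d13_cis") if p.n_d == 11]
        table = manual_table({
            "u": (226.1979 - deuterium_shift(3), 400, 50_000, 50_000),
            "l": (226.1979, 398, 40_000, 100),
        })
        pairs = find_label_pairs(table, TracerDesign("labeled", "control", n_range=(3, 3)))
        annotated = annotate_predictions(pairs, preds, table)
        assert annotated[0].predicted_matches == ()

    def test_no_predictions_leaves_pairs_untagged(self):
        table = manual_table({
            "u": (183.1391, 300, 50_000, 50_000),
            "l": (183.1391 + deuterium_shift(3), 298, 40_000, 100),
        })
        pairs = annotate_predictions(find_label_pairs(table, DESIGN), [], table)
        assert pairs[0].predicted_matches == ()

    def test_pairs_frame_columns(self):
        table = manual_table({
            "u": (183.1391, 300, 50_000, 50_000),
            "l": (183.1391 + deuterium_shift(3), 298, 40_000, 100),
        })
        frame = pairs_to_frame(find_label_pairs(table, DESIGN))
        assert {"unlabeled_id", "labeled_id", "n_deuterium", "mass_error_ppm",
                "delta_rt", "verdict"} <= set(frame.columns)


class TestDesignValidation:
    def test_same_groups_rejected(self):
        with pytest.raises(ValueError):
            TracerDesign("a", "a")

    def test_empty_n_range_rejected(self):
        with pytest.raises(ValueError):
            TracerDesign("a", "b", n_range=(5, 4))
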
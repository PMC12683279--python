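import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import viromarker as vm
import viromarker.profiles as pf
from viromarker.profiles import (
    CONTROL_SUBJECT,
    ObjectType,
    SampleClass,
    Site,
    TimePoint,
    ValidationError,
)
from viromarker.stats import DissimilarityMatrix

from conftest import noiseless_config


def _skin_rec(subject, site, tp):
    return vm.SampleRecord(
        f"{subject}_{site.value}_{tp.value}", subject, SampleClass.SKIN, site, tp
    )


def _obj_rec(subject, obj):
    return vm.SampleRecord(
        f"{subject}_{obj.value}", subject, SampleClass.OBJECT, object_type=obj
    )


def _one_subject_skin(presence_by_tp):
    """Family presence matrix for one subject / one site over three time points."""
    recs = [_skin_rec("S1", Site.FOREHEAD, tp) for tp in pf.TIME_POINTS]
    data = pd.DataFrame(
        [presence_by_tp], index=["famA"], columns=[r.sample_id for r in recs]
    )
    return vm.PresenceMatrix(data), recs


# ---------------------------------------------------------------------------
# stability


def test_family_at_two_timepoints_is_stable():
    presence, recs = _one_subject_skin([1, 0, 1])
    (call,) = vm.site_stability(presence, recs, min_timepoints=2)
    assert call.n_timepoints_detected == 2
    assert call.stable


def test_family_at_one_timepoint_not_stable():
    presence, recs = _one_subject_skin([0, 1, 0])
    (call,) = vm.site_stability(presence, recs, min_timepoints=2)
    assert not call.stable


def test_site_stability_counting_oracle(rng):
    subjects = ["S1", "S2"]
    recs = [
        _skin_rec(s, site, tp)
        for s in subjects
        for site in pf.SITES
        for tp in pf.TIME_POINTS
    ]
    fams = [f"fam{i}" for i in range(6)]
    data = pd.DataFrame(
        (rng.random((6, len(recs))) < 0.5).astype(int),
        index=fams,
        columns=[r.sample_id for r in recs],
    )
    presence = vm.PresenceMatrix(data)
    calls = vm.site_stability(presence, recs, min_timepoints=2)
    assert len(calls) == 2 * 3 * 6
    lookup = {(c.subject_id, c.site, c.family): c for c in calls}
    for s in subjects:
        for site in pf.SITES:
            ids = [f"{s}_{site.value}_{tp.value}" for tp in pf.TIME_POINTS]
            for fam in fams:
                n = int(data.loc[fam, ids].sum())
                c = lookup[(s, site, fam)]
                assert c.n_timepoints_detected == n
                assert c.stable == (n >= 2)


def test_stable_families_single_subject_all_sites():
    calls = [
        vm.StabilityCall("S3", site, "famX", 2, True) for site in pf.SITES
    ]
    assert vm.stable_families(calls, min_subjects=1) == {"famX"}


def test_stable_families_two_sites_excluded():
    calls = [
        vm.StabilityCall(s, site, "famX", 2, True)
        for s in ["S1", "S2"]
        for site in pf.SITES[:2]
    ]
    assert vm.stable_families(calls) == set()


def test_stable_families_loose_mode_pools_subjects():
    # each subject covers one site: strict fails, loose succeeds
    calls = [
        vm.StabilityCall(f"S{i+1}", site, "famX", 3, True)
        for i, site in enumerate(pf.SITES)
    ]
    assert vm.stable_families(calls, require_all_sites=True) == set()
    assert vm.stable_families(calls, require_all_sites=False) == {"famX"}


def test_stable_families_recovers_planted_truth(noiseless_study):
    table, metadata, taxonomy, truth = noiseless_study
    fam = pf.collapse_presence(pf.binarize(table, 1), taxonomy, "family")
    calls = vm.site_stability(fam, metadata, 2)
    stable = vm.stable_families(calls)
    assert stable == truth.signature_families


# ---------------------------------------------------------------------------
# transmissibility


def _transfer_fixture(object_hits, skin_hit=True):
    recs = [_obj_rec("S2", o) for o in pf.OBJECT_TYPES]
    recs.append(_skin_rec("S2", Site.FOREHEAD, TimePoint.T0))
    row = list(object_hits) + [1 if skin_hit else 0]
    data = pd.DataFrame([row], index=["famA"], columns=[r.sample_id for r in recs])
    return vm.PresenceMatrix(data), recs


def test_two_objects_with_host_is_transmissible():
    presence, recs = _transfer_fixture([1, 0, 1, 0])  # cell phone + fabric
    fams, calls = vm.transmissible_families(presence, recs)
    assert fams == {"famA"}
    (call,) = calls
    assert call.n_objects_detected == 2


def test_single_object_not_transmissible():
    presence, recs = _transfer_fixture([0, 1, 0, 0])  # door handle only
    fams, _ = vm.transmissible_families(presence, recs)
    assert fams == set()


def test_host_required_blocks_skinless_family():
    presence, recs = _transfer_fixture([1, 1, 1, 1], skin_hit=False)
    fams, _ = vm.transmissible_families(presence, recs, host_required=True)
    assert fams == set()
    fams_loose, _ = vm.transmissible_families(presence, recs, host_required=False)
    assert fams_loose == {"famA"}


def test_transmissible_counting_oracle(rng):
    subjects = ["S1", "S2", "S3"]
    recs = [_obj_rec(s, o) for s in subjects for o in pf.OBJECT_TYPES]
    recs += [_skin_rec(s, Site.FOREHEAD, TimePoint.T0) for s in subjects]
    fams = [f"fam{i}" for i in range(5)]
    data = pd.DataFrame(
        (rng.random((5, len(recs))) < 0.5).astype(int),
        index=fams,
        columns=[r.sample_id for r in recs],
    )
    presence = vm.PresenceMatrix(data)
    got, calls = vm.transmissible_families(presence, recs, min_objects=2, host_required=True)
    expected = set()
    for fam in fams:
        for s in subjects:
            obj_ids = [f"{s}_{o.value}" for o in pf.OBJECT_TYPES]
            skin_id = f"{s}_forehead_t0"
            if data.loc[fam, obj_ids].sum() >= 2 and data.loc[fam, skin_id] > 0:
                expected.add(fam)
    assert got == expected
    lookup = {(c.subject_id, c.family): c.n_objects_detected for c in calls}
    for fam in fams:
        for s in subjects:
            obj_ids = [f"{s}_{o.value}" for o in pf.OBJECT_TYPES]
            assert lookup[(s, fam)] == int(data.loc[fam, obj_ids].sum())


def test_partial_object_coverage_warns():
    presence, recs = _transfer_fixture([1, 1, 0, 0])
    short = [r for r in recs if r.object_type in (ObjectType.CELL_PHONE, ObjectType.NONE)]
    with pytest.warns(UserWarning, match="object samples"):
        vm.transmissible_families(presence, short)


# ---------------------------------------------------------------------------
# transfer profile


def test_transfer_profile_door_handle_only():
    presence, recs = _transfer_fixture([0, 1, 0, 0])
    calls = [vm.TransferCall("S2", "famA", 1, True)]
    prof = vm.object_transfer_profile(calls, presence, recs)
    assert prof.loc["famA"].tolist() == [0.0, 1.0, 0.0, 0.0]


def test_transfer_profile_fabric_zero():
    presence, recs = _transfer_fixture([1, 1, 0, 1])
    calls = [vm.TransferCall("S2", "famA", 3, True)]
    prof = vm.object_transfer_profile(calls, presence, recs)
    assert prof.loc["famA", "fabric"] == 0.0
    assert prof.loc["famA"].sum() == pytest.approx(1.0)


def test_transfer_profile_brute_tally(rng):
    subjects = ["S1", "S2"]
    recs = [_obj_rec(s, o) for s in subjects for o in pf.OBJECT_TYPES]
    fams = ["famA", "famB"]
    data = pd.DataFrame(
        (rng.random((2, len(recs))) < 0.6).astype(int),
        index=fams,
        columns=[r.sample_id for r in recs],
    )
    presence = vm.PresenceMatrix(data)
    calls = [vm.TransferCall(s, f, 2, True) for s in subjects for f in fams]
    prof = vm.object_transfer_profile(calls, presence, recs)
    for fam in fams:
        tallies = {
            o.value: sum(
                int(data.loc[fam, f"{s}_{o.value}"] > 0) for s in subjects
            )
            for o in pf.OBJECT_TYPES
        }
        total = sum(tallies.values())
        for o in pf.OBJECT_TYPES:
            expected = tallies[o.value] / total if total else 0.0
            assert prof.loc[fam, o.value] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# marker selection & occurrence


def test_select_markers_intersection():
    tax = vm.Taxonomy(
        [
            vm.TaxonLineage("t1", "s1", "B", "C"),
            vm.TaxonLineage("t2", "s2", "B", "C"),
            vm.TaxonLineage("t3", "s3", "A", "C"),
        ]
    )
    presence = vm.PresenceMatrix(
        pd.DataFrame([[1], [1], [1]], index=["s1", "s2", "s3"], columns=["x"])
    )
    fams, species = vm.select_markers({"A", "B"}, {"B", "C"}, presence, tax)
    assert fams == {"B"}
    assert species == {"s1", "s2"}


def test_select_markers_empty_intersection_warns():
    tax = vm.Taxonomy([vm.TaxonLineage("t1", "s1", "A", "C")])
    presence = vm.PresenceMatrix(pd.DataFrame([[1]], index=["s1"], columns=["x"]))
    with pytest.warns(UserWarning, match="empty"):
        fams, species = vm.select_markers({"A"}, {"B"}, presence, tax)
    assert fams == set() and species == set()


def test_occurrence_extremes():
    recs = [
        _skin_rec("S1", site, tp) for site in pf.SITES for tp in pf.TIME_POINTS
    ]
    data = pd.DataFrame(
        [[1] * 9, [0] * 9],
        index=["always", "never"],
        columns=[r.sample_id for r in recs],
    )
    presence = vm.PresenceMatrix(data)
    skin, objs = vm.occurrence_matrix(presence, recs, {"always", "never"})
    assert skin.loc["S1", "always"] == 100.0
    assert skin.loc["S1", "never"] == 0.0


def test_occurrence_brute_tally(default_study):
    table, metadata, taxonomy, truth = default_study
    spp = pf.collapse_presence(pf.binarize(table, 1), taxonomy, "species")
    markers = set(list(truth.signature_species)[:10])
    skin, objs = vm.occurrence_matrix(spp, metadata, markers)
    by_id = pf.records_by_id(metadata)
    for subject in ["S1", "S5"]:
        skin_ids = [
            r.sample_id for r in pf.skin_records(metadata) if r.subject_id == subject
        ]
        obj_ids = [
            r.sample_id for r in pf.object_records(metadata) if r.subject_id == subject
        ]
        for m in markers:
            assert skin.loc[subject, m] == pytest.approx(
                100.0 * spp.data.loc[m, skin_ids].mean()
            )
            assert objs.loc[subject, m] == pytest.approx(
                100.0 * spp.data.loc[m, obj_ids].mean()
            )
    assert ((skin.to_numpy() >= 0) & (skin.to_numpy() <= 100)).all()


# ---------------------------------------------------------------------------
# within/between


def test_within_between_all_identical_samples():
    recs = [
        _skin_rec(s, site, tp)
        for s in ["S1", "S2"]
        for site in pf.SITES[:1]
        for tp in pf.TIME_POINTS
    ]
    ids = [r.sample_id for r in recs]
    d = DissimilarityMatrix(ids, np.zeros((6, 6)))
    res = vm.within_between_skin(d, recs)
    assert all(v == 0.0 for v in res.per_subject_within.values())
    assert all(v == 0.0 for v in res.per_subject_between.values())
    assert res.wilcoxon.p_value == 1.0


def test_within_between_hand_computation():
    recs = [
        _skin_rec("A", Site.FOREHEAD, TimePoint.T0),
        _skin_rec("A", Site.FOREHEAD, TimePoint.T1),
        _skin_rec("B", Site.FOREHEAD, TimePoint.T0),
        _skin_rec("B", Site.FOREHEAD, TimePoint.T1),
    ]
    ids = [r.sample_id for r in recs]
    m = np.array(
        [
            [0.0, 0.2, 0.7, 0.8],
            [0.2, 0.0, 0.6, 0.9],
            [0.7, 0.6, 0.0, 0.4],
            [0.8, 0.9, 0.4, 0.0],
        ]
    )
    res = vm.within_between_skin(DissimilarityMatrix(ids, m), recs)
    assert res.per_subject_within["A"] == pytest.approx(0.2)
    assert res.per_subject_within["B"] == pytest.approx(0.4)
    assert res.per_subject_between["A"] == pytest.approx((0.7 + 0.8 + 0.6 + 0.9) / 4)
    assert res.per_subject_between["B"] == pytest.approx((0.7 + 0.6 + 0.8 + 0.9) / 4)


def test_within_between_objects_identical_profiles():
    recs = [_obj_rec("S1", o) for o in pf.OBJECT_TYPES]
    recs += [_obj_rec("S2", o) for o in pf.OBJECT_TYPES]
    ids = [r.sample_id for r in recs]
    m = np.ones((8, 8)) - np.eye(8)
    m[:4, :4] = 0
    np.fill_diagonal(m, 0)
    res = vm.within_between_objects(DissimilarityMatrix(ids, m), recs)
    assert res.per_subject_within["S1"] == 0.0
    assert res.per_subject_between["S1"] == 1.0


def test_within_between_drops_singleton_subject():
    recs = [
        _skin_rec("A", Site.FOREHEAD, TimePoint.T0),
        _skin_rec("A", Site.FOREHEAD, TimePoint.T1),
        _skin_rec("B", Site.FOREHEAD, TimePoint.T0),
        _skin_rec("B", Site.FOREHEAD, TimePoint.T1),
        _skin_rec("C", Site.FOREHEAD, TimePoint.T0),  # only one sample
    ]
    ids = [r.sample_id for r in recs]
    rng = np.random.default_rng(0)
    m = np.zeros((5, 5))
    iu = np.triu_indices(5, 1)
    m[iu] = rng.random(len(iu[0]))
    m = m + m.T
    with pytest.warns(UserWarning, match="fewer than two"):
        res = vm.within_between_skin(DissimilarityMatrix(ids, m), recs)
    assert set(res.per_subject_within) == {"A", "B"}


def test_signature_model_within_below_between(noiseless_study):
    table, metadata, taxonomy, truth = noiseless_study
    report = vm.run_marker_analysis(table, taxonomy, metadata)
    for s in report.skin_comparison.per_subject_within:
        assert (
            report.skin_comparison.per_subject_within[s]
            < report.skin_comparison.per_subject_between[s]
        )


# ---------------------------------------------------------------------------
# orchestration


def test_noiseless_pipeline_recovers_planted_markers(noiseless_study):
    table, metadata, taxonomy, truth = noiseless_study
    report = vm.run_marker_analysis(table, taxonomy, metadata)
    assert report.marker_families == truth.signature_families
    assert report.marker_species == truth.signature_species
    assert report.marker_families <= report.stable_families
    assert report.marker_families <= report.transmissible_families
    assert len(report.marker_species) == 54
    assert len(report.marker_families) == 15


def test_empty_table_gives_empty_report():
    table = vm.AbundanceTable(pd.DataFrame(index=[], columns=[]).astype(float))
    tax = vm.Taxonomy([])
    with pytest.warns(UserWarning, match="empty"):
        report = vm.run_marker_analysis(table, tax, [])
    assert report.marker_families == set()
    assert report.skin_comparison is None


def test_report_thresholds_echoed(noiseless_study):
    table, metadata, taxonomy, _ = noiseless_study
    cfg = vm.MarkerConfig(min_timepoints=3, min_objects=4)
    report = vm.run_marker_analysis(table, taxonomy, metadata, cfg)
    assert report.config["min_timepoints"] == 3
    assert report.config["min_objects"] == 4


def test_report_json_round_trip(noiseless_study, tmp_path):
    table, metadata, taxonomy, _ = noiseless_study
    report = vm.run_marker_analysis(table, taxonomy, metadata)
    path = tmp_path / "report.json"
    report.save(path)
    back = vm.MarkerReport.load(path)
    assert back.marker_families == report.marker_families
    assert back.marker_species == report.marker_species
    assert back.occurrence_skin.equals(report.occurrence_skin)
    assert back.skin_comparison.wilcoxon.p_value == report.skin_comparison.wilcoxon.p_value
    assert back.config == report.config


def test_filter_monotonicity_small(rng):
    for seed in range(5):
        cfg = vm.StudyConfig(
            seed=900 + seed, detection_prob=0.7, transfer_prob=0.6, transient_rate=0.3
        )
        table, metadata, taxonomy, _ = vm.generate_study(cfg)
        presence = pf.remove_control_taxa(pf.binarize(table, 1), metadata)
        fam = pf.collapse_presence(presence, taxonomy, "family")
        prev = None
        for mt in (1, 2, 3):
            calls = vm.site_stability(fam, metadata, mt)
            stable = vm.stable_families(calls)
            if prev is not None:
                assert stable <= prev
            prev = stable
        prev = None
        for mo in (1, 2, 3, 4):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fams, _ = vm.transmissible_families(fam, metadata, min_objects=mo)
            if prev is not None:
                assert fams <= prev
            prev = fams
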
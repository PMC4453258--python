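"""Shift tracking, the older-taxa artefact rule, and the pipeline."""

from pathlib import Path

import pytest

from nestshift.artefact import (
    PipelineConfig,
    ShiftRecord,
    classify,
    expand_clade,
    older_fraction,
    run_pipeline,
    track_shifts,
)
from nestshift.shiftstats import NullSettings
from nestshift.slicing import AgeTable, TimeBins, nested_series
from nestshift.tree import RootedTree
from nestshift.treeio import write_age_csv, write_tree


def _ages(**fad):
    return AgeTable(fad=dict(fad))


# ----------------------------------------------------------------------
# older_fraction and classify

def test_older_fraction_arithmetic():
    ages = _ages(**{f"x{i}": 1 for i in range(1)}, **{f"y{i}": 2 for i in range(19)})
    clade = frozenset(ages.fad)
    assert older_fraction(clade, ages, 2) == pytest.approx(1 / 20)
    allnew = frozenset(f"y{i}" for i in range(19))
    assert older_fraction(allnew, ages, 2) == 0.0


def test_older_fraction_excludes_unappeared_members():
    ages = _ages(a=1, b=2, c=3, d=3)
    assert older_fraction(frozenset("abcd"), ages, 2) == pytest.approx(0.5)


def test_older_fraction_empty_denominator_errors():
    with pytest.raises(ValueError):
        older_fraction(frozenset({"a"}), _ages(a=3), 2)


def _record(clade, first_bin):
    return ShiftRecord(clade=frozenset(clade), first_bin=first_bin, bins_detected={first_bin})


def test_classify_boundary_is_genuine():
    # exactly 10% older: 1 of 10 occurring members predates the bin
    ages = _ages(old0=1, **{f"n{i}": 2 for i in range(9)})
    rec = classify([_record(set(ages.fad), 2)], ages, threshold=0.10)[0]
    assert rec.older_fraction == pytest.approx(0.10)
    assert rec.status == "genuine"


def test_classify_three_of_ten_older_is_artefact():
    ages = _ages(**{f"o{i}": 1 for i in range(3)}, **{f"n{i}": 2 for i in range(7)})
    rec = classify([_record(set(ages.fad), 2)], ages, threshold=0.10)[0]
    assert rec.older_fraction == pytest.approx(0.30)
    assert rec.status == "artefact"


def test_classify_monotone_in_threshold():
    ages = _ages(**{f"o{i}": 1 for i in range(3)}, **{f"n{i}": 2 for i in range(7)})
    records = [_record(set(ages.fad), 2)]
    prev = set()
    for thr in (0.0, 0.1, 0.3, 0.5, 1.0):
        out = classify([_record(set(ages.fad), 2)], ages, threshold=thr)
        genuine = {r.first_bin for r in out if r.status == "genuine"}
        assert prev <= genuine or genuine == prev
        prev = genuine
    assert classify(records, ages, threshold=1.0)[0].status == "genuine"


def test_all_new_members_always_genuine():
    ages = _ages(**{f"n{i}": 3 for i in range(12)})
    rec = classify([_record(set(ages.fad), 3)], ages, threshold=0.0)[0]
    assert rec.status == "genuine"


# ----------------------------------------------------------------------
# tracking

def _series_for_tracking():
    tree = RootedTree.from_nested(((("A", "B"), ("C", "D")), ("E", "F")))
    ages = _ages(A=1, B=2, C=3, D=3, E=1, F=2)
    bins = TimeBins(("x", "y", "z"))
    return nested_series(tree, ages, bins)


def test_track_merges_same_stem_across_bins():
    series = _series_for_tracking()
    abcd = frozenset("ABCD")
    per_bin = [(2, [frozenset({"A", "B", "GHOST:C"})]), (3, [abcd])]
    records = track_shifts(per_bin, series)
    assert len(records) == 1
    assert records[0].clade == abcd
    assert records[0].first_bin == 2
    assert records[0].bins_detected == {2, 3}


def test_track_disjoint_clades_separate_records():
    series = _series_for_tracking()
    per_bin = [(3, [frozenset({"A", "B"}), frozenset({"E", "F"})])]
    records = track_shifts(per_bin, series)
    assert len(records) == 2


def test_track_punctual_detection():
    series = _series_for_tracking()
    per_bin = [(2, [frozenset({"A", "B", "GHOST:C"})]), (3, [])]
    records = track_shifts(per_bin, series)
    assert records[0].bins_detected == {2}


def test_track_order_independent():
    series = _series_for_tracking()
    abcd = frozenset("ABCD")
    pb1 = [(2, [frozenset({"A", "B", "GHOST:C"})]), (3, [abcd])]
    pb2 = list(reversed(pb1))
    a = track_shifts(pb1, series)
    b = track_shifts(pb2, series)
    assert [(r.clade, r.first_bin, r.bins_detected) for r in a] == [
        (r.clade, r.first_bin, r.bins_detected) for r in b
    ]


def test_expand_clade_ghosts():
    ghosts = {"GHOST:C": frozenset({"C", "D"})}
    assert expand_clade(frozenset({"A", "GHOST:C"}), ghosts) == frozenset({"A", "C", "D"})


# ----------------------------------------------------------------------
# pipeline end to end

def _balanced(labels):
    if len(labels) == 1:
        return labels[0]
    half = len(labels) // 2
    return (_balanced(labels[:half]), _balanced(labels[half:]))


def _pipeline_inputs(tmp_path, older_in_radiation=0):
    """Comb of early taxa with a balanced radiation appearing at bin 3.

    ``older_in_radiation`` moves that many radiation members into bin 1,
    which drives the older-taxa fraction past the artefact threshold.
    """
    radiation = [f"r{i:02d}" for i in range(32)]
    nested = _balanced(radiation)
    for i in range(6):
        nested = (f"old{i}", nested)
    tree = RootedTree.from_nested(nested)
    bins = ["b1", "b2", "b3", "b4"]
    fad = {f"old{i}": 1 + (i % 2) for i in range(6)}
    for i, r in enumerate(radiation):
        fad[r] = 1 if i < older_in_radiation else 3
    ages = {t: [bins[b - 1]] for t, b in fad.items()}
    tree_path = tmp_path / "tree.nwk"
    ages_path = tmp_path / "ages.csv"
    tree_path.write_text(write_tree(tree))
    ages_path.write_text(write_age_csv(ages))
    return PipelineConfig(
        tree_path=str(tree_path),
        ages_path=str(ages_path),
        bins=TimeBins(tuple(bins)),
        null=NullSettings(null_trees=400, alpha=0.05, seed=5),
        out_dir=str(tmp_path / "out"),
    ), frozenset(radiation)


def test_pipeline_detects_genuine_radiation(tmp_path):
    config, radiation = _pipeline_inputs(tmp_path)
    report = run_pipeline(config)
    recs = [r for r in report.records if r.clade == radiation]
    assert recs and recs[0].status == "genuine"
    assert recs[0].first_bin == 3
    assert recs[0].older_fraction == 0.0
    out = Path(config.out_dir)
    for name in ("shifts.tsv", "summary.tsv", "ghosts.tsv", "manifest.json"):
        assert (out / name).exists()


def test_pipeline_flags_extinction_artefact(tmp_path):
    """>10% of the radiation's members predate first detection -> artefact."""
    config, radiation = _pipeline_inputs(tmp_path, older_in_radiation=8)
    report = run_pipeline(config)
    recs = [r for r in report.records if r.clade == radiation]
    assert recs
    assert recs[0].older_fraction > 0.10
    assert recs[0].status == "artefact"


def test_pipeline_rerun_byte_identical(tmp_path):
    config, _ = _pipeline_inputs(tmp_path)
    run_pipeline(config)
    first = {
        p.name: p.read_bytes() for p in Path(config.out_dir).iterdir()
    }
    run_pipeline(config)
    second = {
        p.name: p.read_bytes() for p in Path(config.out_dir).iterdir()
    }
    assert first == second


def test_pipeline_null_dataset_usually_empty(tmp_path):
    """A pure-Yule dataset with no planted shift yields no genuine record."""
    from nestshift.synthetic import SimSpec, fossilize, yule_tree
    from nestshift import treeio

    spec = SimSpec(n_tips=32, sampling_rate=3.0, seed=77)
    tree = yule_tree(spec)
    bins = TimeBins(tuple(f"b{i}" for i in range(1, 11)))
    ages, _ = fossilize(tree, spec, bins=bins, lineage_path=True)
    names = dict(enumerate(bins.names, start=1))
    raw = {t: [names[ages.fad[t]]] for t in ages.fad}
    (tmp_path / "tree.nwk").write_text(write_tree(tree))
    (tmp_path / "ages.csv").write_text(write_age_csv(raw))
    config = PipelineConfig(
        tree_path=str(tmp_path / "tree.nwk"),
        ages_path=str(tmp_path / "ages.csv"),
        bins=bins,
        null=NullSettings(null_trees=300, alpha=0.05, seed=1),
        out_dir=str(tmp_path / "out"),
    )
    report = run_pipeline(config)
    assert len(report.records) <= 1
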
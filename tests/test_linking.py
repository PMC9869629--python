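from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from classlink.cooccurrence import CandidateLink
from classlink.formats import read_validated_links
from classlink.linking import (
    aggregate_percent_decreases,
    evaluate_validated_links,
    filter_links_by_class,
    links_per_gcf,
    percent_decrease,
    rank_links,
    summarize_reduction,
    threshold_sweep,
)
from classlink.scoring import ScoreResult
from classlink.tables import EmptyInputError

DATA = Path(__file__).parent / "data"


def make_link(gcf, obj, metcalf, score):
    cs = ScoreResult(score=score) if score is not None else ScoreResult(score=None)
    return CandidateLink(gcf_id=gcf, object_id=obj, metcalf=metcalf, classscore=cs)


def test_filter_threshold_is_inclusive():
    links = [
        make_link("g", "a", 5, 0.78),
        make_link("g", "b", 5, 0.26),
        make_link("g", "c", 5, 0.24),
        make_link("g", "d", 5, None),
    ]
    kept = filter_links_by_class(links, 0.25, filter_missing=True)
    assert [l.object_id for l in kept] == ["a", "b"]
    kept_lenient = filter_links_by_class(links, 0.25, filter_missing=False)
    assert [l.object_id for l in kept_lenient] == ["a", "b", "d"]
    # score exactly at the cut-off is kept
    assert filter_links_by_class([make_link("g", "x", 5, 0.25)], 0.25)


def test_filter_vacuous_at_zero_cutoff():
    links = [make_link("g", "a", 5, 0.0), make_link("g", "b", 5, None)]
    assert filter_links_by_class(links, 0.0, filter_missing=False) == links


def test_competition_ranking():
    links = [
        make_link("g", "a", 12.4, 0.9),
        make_link("g", "b", 12.4, 0.9),
        make_link("g", "c", 9.0, 0.9),
    ]
    rank_links(links)
    assert [(l.rank_before, l.shared_before) for l in links] == [(1, 1), (1, 1), (3, 0)]


def test_thirteen_way_tie_reports_shared_twelve():
    links = [make_link("g", f"s{i}", 12.4, 0.9) for i in range(13)]
    rank_links(links)
    assert all(l.rank_before == 1 and l.shared_before == 12 for l in links)


def test_ranks_match_sorting_oracle():
    rng = np.random.default_rng(31)
    links = [make_link("g", f"s{i}", float(rng.choice([1.0, 2.5, 3.7, 9.9])), 0.5)
             for i in range(40)]
    rank_links(links)
    scores = sorted((l.metcalf for l in links), reverse=True)
    for link in links:
        assert link.rank_before == scores.index(link.metcalf) + 1


def test_ranking_is_per_gcf():
    links = [make_link("g1", "a", 5.0, 0.9), make_link("g2", "b", 9.0, 0.9)]
    rank_links(links)
    assert links[0].rank_before == 1 and links[1].rank_before == 1


def test_rank_after_never_worse_than_before():
    rng = np.random.default_rng(7)
    links = [make_link("g", f"s{i}", float(rng.normal(5, 2)), float(rng.random()))
             for i in range(60)]
    rank_links(links, stage="before")
    survivors = filter_links_by_class(links, 0.25)
    rank_links(survivors, stage="after")
    for link in survivors:
        assert link.rank_after <= link.rank_before


def test_percent_decrease_of_the_mean():
    assert round(percent_decrease(550, 177)) == 68
    assert round(percent_decrease(206, 64)) == 69
    assert percent_decrease(10, 10) == 0.0
    with pytest.raises(ValueError):
        percent_decrease(0, 0)


def test_mean_of_per_dataset_decreases():
    assert round(aggregate_percent_decreases([68, 53, 69])) == 63
    # computed from the printed dataset means, the mean decrease also rounds to 63
    computed = [percent_decrease(550, 177), percent_decrease(27, 13), percent_decrease(206, 64)]
    assert round(aggregate_percent_decreases(computed)) == 63


def test_summarize_reduction_counts():
    before = {"g1": 10, "g2": 4, "g3": 0}
    after = {"g1": 5, "g2": 4}
    s = summarize_reduction(before, after)
    assert s.per_gcf["g1"] == (10, 5, 50.0)
    assert "g3" not in s.per_gcf  # zero-before excluded from percentages
    assert s.mean_pct_decrease == pytest.approx(25.0)
    assert s.mean_before == pytest.approx(14 / 3)
    assert s.pct_decrease_of_mean == pytest.approx(percent_decrease(14 / 3, 3.0))
    hist = s.histogram
    assert hist["n_gcfs_before"].sum() == 3
    with pytest.raises(ValueError):
        summarize_reduction({"g": 2}, {"g": 3})


def test_validated_links_table_statistics():
    """The transcribed validated-link table reproduces the published summary:
    23/24 scored links pass the 0.25 cut-off (96%), 12 links are rank 1
    after filtering vs 5 before."""
    table = read_validated_links(DATA / "validated_links_podp.tsv")
    report = evaluate_validated_links(table, 0.25)
    assert report.n_scored == 24
    assert report.n_passing_class_threshold == 23
    assert round(report.retention_pct) == 96
    assert report.n_rank1_after == 12
    assert report.n_rank1_before == 5
    statuses = report.rows["status"]
    assert (statuses == "not_found").sum() == 2
    assert (statuses == "discarded_classscore").sum() == 1
    assert (statuses == "discarded_metcalf").sum() == 5
    assert (statuses == "retained").sum() == 18
    # the single class-score failure scores 0.03
    failing = report.rows[statuses == "discarded_classscore"]
    assert failing["npclassscore"].iloc[0] == pytest.approx(0.03)


def test_evaluate_all_below_cutoff():
    table = read_validated_links(DATA / "validated_links_podp.tsv")
    report = evaluate_validated_links(table, 1.01)
    assert report.n_passing_class_threshold == 0
    assert report.retention_pct == 0.0


def test_evaluate_empty_raises():
    with pytest.raises(EmptyInputError):
        evaluate_validated_links(pd.DataFrame())


def test_threshold_sweep_monotone():
    rng = np.random.default_rng(13)
    links = [
        make_link(f"g{i % 5}", f"s{i}", float(rng.normal(5, 1)),
                  None if i % 11 == 0 else float(rng.random()))
        for i in range(120)
    ]
    truth = [(l.gcf_id, l.object_id) for l in links[:10]]
    sweep = threshold_sweep(links, [0.0, 0.25, 0.5, 0.75, 1.01], filter_missing=True,
                            true_links=truth)
    assert list(sweep["n_links"]) == sorted(sweep["n_links"], reverse=True)
    assert list(sweep["retained_true_links"]) == sorted(
        sweep["retained_true_links"], reverse=True
    )
    # cutoff above 1 keeps nothing when missing scores are filtered
    assert sweep["n_links"].iloc[-1] == 0


def test_threshold_sweep_boundary_cutoffs_with_missing_exempt():
    links = [make_link("g", "a", 5, 0.4), make_link("g", "b", 5, None)]
    sweep = threshold_sweep(links, [0.0, 1.01], filter_missing=False)
    assert sweep["n_links"].iloc[0] == 2  # no filtering
    assert sweep["n_links"].iloc[1] == 1  # only the MISSING-exempt link survives
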
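"""The anonymise-until-safe loop: mandatory steps, greedy search, reports,
failure modes and replay."""

import json

import numpy as np
import pandas as pd
import pytest

from trialanon import engine, riskmodel, transforms
from trialanon.codebook import codebook_from_dict
from trialanon.engine import CannotCertifyError, PlanStep, TransformPlan


def make_ctx(v, level="high"):
    cfg = riskmodel.default_context_config()
    answers = {i: level for items in cfg["groups"].values() for i in items}
    return riskmodel.context_from_checklist(answers, v=v)


@pytest.fixture(scope="module")
def pooled(world):
    return {name: world.pooled(name)
            for name in ("demography", "visits", "scores", "events")}


@pytest.fixture(scope="module")
def run(world, pooled):
    ctx = make_ctx(world.truth["v"])
    released, link, report = engine.anonymise(
        pooled, world.codebook, ctx, seed=11)
    return {"released": released, "link": link, "report": report, "ctx": ctx}


class TestMandatorySteps:
    def test_subject_ids_pseudonymised_consistently(self, pooled, run):
        link = run["link"]
        originals = set(pooled["demography"]["subject_id"].astype(str))
        assert set(link.mapping) == originals
        for name, df in run["released"].items():
            assert set(df["subject_id"]) <= set(link.mapping.values())
            assert not set(df["subject_id"]) & originals

    def test_dates_replaced_by_relative_days(self, run):
        rel = run["released"]
        assert "enrollment_date" not in rel["demography"].columns
        assert "enrollment_day" in rel["demography"].columns
        assert "visit_date" not in rel["visits"].columns
        days = rel["visits"]["visit_day"].dropna().astype(int)
        assert (days != 0).all()  # no day 0 anywhere

    def test_reference_is_subjects_earliest_date(self, run):
        # earliest date per subject maps to day 1, so the minimum across a
        # subject's day columns is exactly 1
        rel = run["released"]
        mins = {}
        for name, col in (("demography", "enrollment_day"),
                          ("visits", "visit_day"), ("events", "event_day")):
            for sid, d in zip(rel[name]["subject_id"], rel[name][col]):
                if pd.notna(d):
                    mins[sid] = min(mins.get(sid, 10**9), int(d))
        assert set(mins.values()) == {1}

    def test_direct_identifiers_suppressed(self, run):
        assert "site_id" not in run["released"]["demography"].columns


class TestCertification:
    def test_release_is_certified_under_strict_average(self, run):
        ra = run["report"].final
        assert run["report"].status == "certified"
        assert ra.certified and ra.strict_average_ok
        assert ra.overall <= riskmodel.RISK_THRESHOLD

    def test_trajectory_non_increasing(self, run):
        overall = [t["overall"] for t in run["report"].trajectory]
        assert all(b <= a + 1e-12 for a, b in zip(overall, overall[1:]))

    def test_trajectory_records_each_step(self, run):
        traj = run["report"].trajectory
        assert traj[0]["iteration"] == 0 and traj[0]["variable"] is None
        for i, t in enumerate(traj):
            assert t["iteration"] == i
        for t in traj[1:]:
            assert t["variable"] is not None and t["step"] is not None

    def test_report_json_roundtrip_and_text(self, run):
        doc = json.loads(run["report"].to_json())
        assert doc["status"] == "certified"
        assert doc["final"]["overall"] == run["report"].final.overall
        text = run["report"].to_text()
        assert "Risk trajectory" in text and "certified" in text


class TestReplay:
    def test_replay_reproduces_release_byte_identically(self, world, pooled, run):
        replayed = engine.replay(pooled, run["report"].log, world.codebook,
                                 run["link"])
        assert set(replayed) == set(run["released"])
        for name in replayed:
            assert replayed[name].to_csv(index=False) == \
                run["released"][name].to_csv(index=False)

    def test_replayed_release_recomputes_same_risk(self, world, run):
        """The report's final numbers are recoverable from the released
        files alone."""
        view = engine._subject_qi_view(
            run["released"], world.codebook, "subject_id").reset_index()
        ra, dr_pub, dr_acq = engine._assess_view(
            view, run["released"], world.codebook, run["ctx"], "subject_id",
            riskmodel.RISK_THRESHOLD, True)
        final = run["report"].final
        assert ra.overall == pytest.approx(final.overall, abs=1e-12)
        assert (ra.t1, ra.t2, ra.t3) == pytest.approx(
            (final.t1, final.t2, final.t3), abs=1e-12)


class TestDeterminism:
    def test_identical_seeds_identical_outputs(self, world, pooled):
        ctx = make_ctx(world.truth["v"])
        r1 = engine.anonymise(pooled, world.codebook, ctx, seed=11)
        r2 = engine.anonymise(pooled, world.codebook, ctx, seed=11)
        for name in r1[0]:
            assert r1[0][name].to_csv(index=False) == \
                r2[0][name].to_csv(index=False)
        assert r1[1].mapping == r2[1].mapping
        assert r1[2].to_json() == r2[2].to_json()

    def test_different_seed_changes_pseudonyms_not_verdict(self, world, pooled):
        ctx = make_ctx(world.truth["v"])
        r1 = engine.anonymise(pooled, world.codebook, ctx, seed=11)
        r2 = engine.anonymise(pooled, world.codebook, ctx, seed=12)
        assert r1[1].mapping != r2[1].mapping
        assert r1[2].status == r2[2].status == "certified"
        assert r1[2].final.overall == pytest.approx(r2[2].final.overall)


SMALL_CB = {
    "tables": [{
        "name": "demography", "key": "subject_id", "subject_table": True,
        "variables": [
            {"name": "subject_id", "privacy_class": "direct_identifier",
             "value_type": "text"},
            {"name": "age", "privacy_class": "quasi_public",
             "value_type": "integer", "range": [0, 120]},
            {"name": "sex", "privacy_class": "quasi_public",
             "value_type": "category", "categories": ["M", "F"]},
        ],
    }]
}


class TestFailureModes:
    def test_single_record_cannot_certify(self):
        """One subject is always an equivalence class of one: the ladders
        exhaust and the run fails with the report attached."""
        cb = codebook_from_dict(SMALL_CB)
        tables = {"demography": pd.DataFrame(
            {"subject_id": ["a"], "age": [40], "sex": ["F"]})}
        with pytest.raises(CannotCertifyError) as err:
            engine.anonymise(tables, cb, make_ctx(0.5), seed=0)
        report = err.value.report
        assert report.status == "not_certified"
        assert report.trajectory  # partial trajectory preserved

    def test_validation_failure_is_fatal(self, world):
        bad = {"demography": pd.DataFrame({"subject_id": ["a"]})}
        with pytest.raises(engine.EngineError, match="validation"):
            engine.anonymise(bad, world.codebook, make_ctx(0.1), seed=0)

    def test_empty_ladder_plan_with_risky_data_fails(self):
        cb = codebook_from_dict(SMALL_CB)
        rng = np.random.default_rng(0)
        tables = {"demography": pd.DataFrame({
            "subject_id": [str(i) for i in range(20)],
            "age": rng.integers(20, 80, size=20),
            "sex": rng.choice(["M", "F"], size=20),
        })}
        plan = TransformPlan(ladders={})
        with pytest.raises(CannotCertifyError, match="exhausted"):
            engine.anonymise(tables, cb, make_ctx(0.9), plan=plan, seed=0)


class TestPlans:
    def test_default_plan_shapes(self, world):
        plan = engine.default_plan(world.codebook, "demography")
        age = plan.ladders["age"]
        assert [s.kind for s in age] == ["generalize_numeric"] * 3 + \
            ["suppress_column"]
        assert [s.param_dict.get("width") for s in age[:3]] == [5, 10, 20]
        country = plan.ladders["country"]
        assert [s.kind for s in country] == [
            "generalize_categorical", "generalize_categorical",
            "suppress_column"]
        assert [s.param_dict.get("level") for s in country[:2]] == [1, 2]

    def test_utility_breaks_ties_toward_less_valuable_variable(self):
        """Two identically distributed QIs: the one with the lower utility
        weight is transformed first."""
        cb = codebook_from_dict({
            "tables": [{
                "name": "demography", "key": "subject_id",
                "subject_table": True,
                "variables": [
                    {"name": "subject_id",
                     "privacy_class": "direct_identifier",
                     "value_type": "text"},
                    {"name": "a", "privacy_class": "quasi_public",
                     "value_type": "integer"},
                    {"name": "b", "privacy_class": "quasi_public",
                     "value_type": "integer"},
                ],
            }]
        })
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 50, size=60)
        tables = {"demography": pd.DataFrame({
            "subject_id": [str(i) for i in range(60)],
            "a": vals, "b": vals})}
        plan = engine.default_plan(cb, "demography", utility={"a": 5.0, "b": 1.0})
        try:
            _, _, report = engine.anonymise(
                tables, cb, make_ctx(0.5), plan=plan, seed=0)
            traj = report.trajectory
        except CannotCertifyError as err:
            traj = err.value.report.trajectory if hasattr(err, "value") \
                else err.report.trajectory
        first = next(t for t in traj if t["variable"] is not None)
        assert first["variable"] == "b"

    def test_step_seed_in_range_and_distinct(self):
        seeds = {engine._step_seed(1, v, i)
                 for v in ("age", "country") for i in range(5)}
        assert len(seeds) == 10
        assert all(0 <= s < 2**31 for s in seeds)


class TestSuppressedCellAccounting:
    def test_suppress_cells_step_logged_and_counted(self):
        cb = codebook_from_dict(SMALL_CB)
        rng = np.random.default_rng(1)
        n = 60
        tables = {"demography": pd.DataFrame({
            "subject_id": [str(i) for i in range(n)],
            "age": rng.integers(30, 40, size=n),
            "sex": rng.choice(["M", "F"], size=n),
        })}
        plan = TransformPlan(ladders={
            "age": [PlanStep.make("generalize_numeric", width=10, anchor=0,
                                  integer=True),
                    PlanStep.make("suppress_column")],
            "sex": [PlanStep.make("suppress_cells", min_count=100)],
        })
        try:
            _, _, report = engine.anonymise(tables, cb, make_ctx(0.2),
                                            plan=plan, seed=0)
        except CannotCertifyError as err:
            report = err.report
        if report.suppressed_cell_counts:
            assert set(report.suppressed_cell_counts) == {"sex"}
            logged = report.log.suppressed_cells()
            assert len(logged) == report.suppressed_cell_counts["sex"]
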
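import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_gene
from genesnap.campaign import (Action, Response, SolicitationRequest,
                               TemplateError, apply_action, build_batches,
                               load_requests, next_action, percent,
                               record_response, render_email, save_requests,
                               stage_table, summarize_campaign,
                               unique_snapshots, DEFAULT_TEMPLATE)
from genesnap.config import CampaignPolicy
from genesnap.corpus import Author, Corpus, Snapshot
from genesnap.expert_rank import Assignment, ExpertScore
from genesnap.synthetic import simulate_responses

DAY0 = dt.date(2016, 5, 1)


def make_assignments(n_genes, author_id="aX"):
    return {
        f"g{i:03d}": Assignment(
            gene_id=f"g{i:03d}",
            ranked_authors=[(author_id, ExpertScore(raw=9.0, display=9))],
        )
        for i in range(n_genes)
    }


def corpus_for(assignments):
    genes = {gid: make_gene(gid) for gid in assignments}
    return Corpus(genes=genes, publications={},
                  authors={"aX": Author("aX", "Xu")})


class TestBuildBatches:
    def test_author_with_no_genes_gets_no_messages(self):
        assert build_batches({}, Corpus(), DAY0) == []

    def test_five_genes_individual_one_week(self):
        assignments = make_assignments(5)
        (batch,) = build_batches(assignments, corpus_for(assignments), DAY0)
        assert batch.kind == "individual"
        assert len(batch.requests) == 5
        assert all(r.deadline_days == 7 for r in batch.requests)
        assert batch.manifest is None

    def test_six_genes_single_spreadsheet_four_weeks(self):
        assignments = make_assignments(6)
        (batch,) = build_batches(assignments, corpus_for(assignments), DAY0)
        assert batch.kind == "spreadsheet"
        assert len(batch.requests) == 6
        assert all(r.deadline_days == 28 for r in batch.requests)
        assert list(batch.manifest.columns) == ["gene_id", "symbol", "name",
                                                "snapshot_text"]
        assert len(batch.manifest) == 6
        assert (batch.manifest["snapshot_text"] == "").all()

    def test_unassignable_genes_skipped(self):
        assignments = make_assignments(2)
        assignments["gXX"] = Assignment("gXX", [], status="unassignable")
        corpus = corpus_for({k: None for k in ("g000", "g001", "gXX")})
        (batch,) = build_batches(assignments, corpus, DAY0)
        assert len(batch.requests) == 2


class TestRenderEmail:
    def _request(self):
        return SolicitationRequest("g1", "a1", "individual", DAY0, 7)

    def test_placeholders_substituted(self):
        gene = make_gene("g1")
        gene.symbol, gene.name = "wg", "wingless"
        author = Author("a1", "Smith")
        out = render_email(self._request(), gene, author,
                           "Dear Dr {surname}, re {symbol} ({name}): {form_link}")
        assert out.startswith("Dear Dr Smith, re wg (wingless): https://")
        assert "{" not in out

    def test_missing_optional_summary_renders_omission_line(self):
        gene = make_gene("g1")
        author = Author("a1", "Smith")
        out = render_email(self._request(), gene, author, DEFAULT_TEMPLATE)
        assert "no Interactive Fly summary" in out
        assert "{" not in out

    def test_present_summary_is_included(self):
        gene = make_gene("g1")
        gene.interactive_fly_summary = "Acts in wing development."
        author = Author("a1", "Smith")
        out = render_email(self._request(), gene, author,
                           "IF: {interactive_fly_summary}")
        assert out == "IF: Acts in wing development."

    def test_unknown_placeholder_named_in_error(self):
        with pytest.raises(TemplateError, match="bogus"):
            render_email(self._request(), make_gene("g1"), Author("a1", "S"),
                         "Hello {bogus}")


class TestNextAction:
    def _req(self, status="pending", deadline=7, rank=0):
        r = SolicitationRequest("g1", "a1", "individual", DAY0, deadline,
                                author_rank=rank)
        r.status = status
        return r

    def test_pending_past_deadline_first_reminder(self):
        assert next_action(self._req(), DAY0 + dt.timedelta(days=8)) \
            is Action.FIRST_REMINDER

    def test_pending_on_deadline_waits(self):
        assert next_action(self._req(), DAY0 + dt.timedelta(days=7)) is Action.WAIT

    def test_submitted_is_terminal(self):
        assert next_action(self._req("submitted"), DAY0 + dt.timedelta(days=99)) \
            is Action.NONE

    def test_one_reminder_policy_escalates_after_first(self):
        r = self._req()
        apply_action(r, Action.FIRST_REMINDER, DAY0 + dt.timedelta(days=8))
        policy = CampaignPolicy(max_reminders=1)
        assert next_action(r, DAY0 + dt.timedelta(days=16), policy) is Action.ESCALATE

    def test_two_reminder_policy_sends_second_then_escalates(self):
        r = self._req()
        apply_action(r, Action.FIRST_REMINDER, DAY0 + dt.timedelta(days=8))
        assert next_action(r, DAY0 + dt.timedelta(days=16)) is Action.SECOND_REMINDER
        apply_action(r, Action.SECOND_REMINDER, DAY0 + dt.timedelta(days=16))
        assert next_action(r, DAY0 + dt.timedelta(days=24)) is Action.ESCALATE

    def test_bounced_escalates_immediately(self):
        assert next_action(self._req("bounced"), DAY0) is Action.ESCALATE

    def test_deadline_override_respected(self):
        r = self._req()
        r.deadline_override = 14
        assert next_action(r, DAY0 + dt.timedelta(days=10)) is Action.WAIT
        assert next_action(r, DAY0 + dt.timedelta(days=15)) is Action.FIRST_REMINDER

    def test_spreadsheet_deadline_is_four_weeks(self):
        r = SolicitationRequest("g1", "a1", "spreadsheet", DAY0, 28)
        assert next_action(r, DAY0 + dt.timedelta(days=28)) is Action.WAIT
        assert next_action(r, DAY0 + dt.timedelta(days=29)) is Action.FIRST_REMINDER


class TestRecordResponse:
    def _req(self):
        return SolicitationRequest("g1", "a1", "individual", DAY0, 7)

    def test_snapshot_submits_and_emits_record(self):
        r = self._req()
        snap = record_response(r, Response("g1", "a1", "snapshot", DAY0,
                                           text="Acts in Wnt signaling."),
                               contributor="Smith")
        assert r.status == "submitted"
        assert r.submitted_stage == "initial"
        assert snap == Snapshot("g1", "Acts in Wnt signaling.", "Smith",
                                DAY0.isoformat())

    @pytest.mark.parametrize("kind", ["decline", "not_my_gene", "too_busy"])
    def test_declines_map_to_declined(self, kind):
        r = self._req()
        assert record_response(r, Response("g1", "a1", kind, DAY0)) is None
        assert r.status == "declined"

    def test_bounce_then_escalatable(self):
        r = self._req()
        record_response(r, Response("g1", "a1", "bounce", DAY0))
        assert r.status == "bounced"
        assert next_action(r, DAY0) is Action.ESCALATE

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            record_response(self._req(), Response("g2", "a1", "decline", DAY0))

    def test_duplicate_after_submission_keeps_status_appends_history(self):
        r = self._req()
        record_response(r, Response("g1", "a1", "snapshot", DAY0, text="v1"))
        n_events = len(r.history)
        snap = record_response(r, Response("g1", "a1", "snapshot",
                                           DAY0 + dt.timedelta(days=3), text="v2"))
        assert r.status == "submitted"
        assert len(r.history) == n_events + 1
        assert snap is not None  # duplicate kept; deduplicated downstream

    def test_reminder_stage_recorded_on_submission(self):
        r = self._req()
        apply_action(r, Action.FIRST_REMINDER, DAY0 + dt.timedelta(days=8))
        record_response(r, Response("g1", "a1", "snapshot",
                                    DAY0 + dt.timedelta(days=9), text="t"))
        assert r.submitted_stage == "first_reminder"


class TestSummaries:
    def test_percent_matches_published_arithmetic(self):
        assert percent(496, 1690) == 29
        assert percent(1580, 4775) == 33
        assert percent(1580, 13907) == 11

    def test_zero_denominator_is_not_applicable(self):
        assert percent(0, 0) is None
        table = stage_table([("initial", 0, 0)])
        assert table.loc[0, "percent"] is None

    def test_numerators_bounded_and_percent_in_range(self, request_factory):
        reqs = request_factory(200)
        result = simulate_responses(reqs, (0.4, 0.3, 0.2, 0.3), seed=9)
        table = summarize_campaign(result.requests)
        assert (table["n_received"] <= table["n_emailed"]).all()
        for p in table["percent"]:
            assert p is None or 0 <= p <= 100

    def test_unique_snapshots_keeps_earliest_per_gene(self):
        snaps = [
            Snapshot("g1", "late", "A", "2016-06-10"),
            Snapshot("g1", "early", "B", "2016-06-01"),
            Snapshot("g2", "only", "C", "2016-06-05"),
        ]
        unique = unique_snapshots(snaps)
        assert len(unique) == 2
        (g1,) = [s for s in unique if s.gene_id == "g1"]
        assert g1.text == "early"

    def test_unique_snapshots_empty(self):
        assert unique_snapshots([]) == []


class TestLedgerPersistence:
    def test_requests_round_trip(self, tmp_path, request_factory):
        reqs = request_factory(5)
        apply_action(reqs[0], Action.FIRST_REMINDER, DAY0 + dt.timedelta(days=8))
        record_response(reqs[1], Response(reqs[1].gene_id, reqs[1].author_id,
                                          "snapshot", DAY0, text="t"))
        reqs[2].deadline_override = 14
        path = tmp_path / "ledger.tsv"
        save_requests(reqs, path)
        loaded = load_requests(path)
        assert [(r.gene_id, r.status, r.history, r.deadline_override,
                 r.submitted_stage) for r in loaded] == \
            [(r.gene_id, r.status, r.history, r.deadline_override,
              r.submitted_stage) for r in reqs]


class TestSimulatedCampaign:
    def test_zero_probabilities_yield_zero_snapshots(self, request_factory):
        result = simulate_responses(request_factory(50), (0, 0, 0, 0), seed=1)
        assert result.snapshots == []
        # every first-author request escalated, every successor closed unanswered
        originals = [r for r in result.requests if r.author_rank == 0]
        assert all(r.status == "escalated" for r in originals)

    def test_certain_response_submits_before_any_reminder(self, request_factory):
        result = simulate_responses(request_factory(50), (1, 1, 1, 1), seed=1)
        assert len(result.snapshots) == 50
        assert all(r.submitted_stage == "initial" for r in result.requests)
        assert all("first_reminder" not in {e for _, e in r.history}
                   for r in result.requests)

    def test_stage_rates_track_probabilities(self, request_factory):
        probs = (0.29, 0.32, 0.11, 0.30)
        result = simulate_responses(request_factory(1200), probs, seed=42)
        table = summarize_campaign(result.requests).set_index("stage")
        for stage, p in zip(("initial", "first_reminder", "second_reminder",
                             "second_author"), probs):
            n = table.loc[stage, "n_emailed"]
            rate = table.loc[stage, "n_received"] / n
            assert abs(rate - p) < 4 * (p * (1 - p) / n) ** 0.5

    def test_every_request_terminates_within_bounded_periods(self, request_factory):
        policy = CampaignPolicy(max_reminders=2)
        reqs = request_factory(80)
        result = simulate_responses(reqs, (0.2, 0.2, 0.2, 0.2), seed=3,
                                    policy=policy)
        # ≤ (max_reminders + 2) periods per ranked author, 2 ranks, +1 day slack each
        bound = (policy.max_reminders + 2) * 2 * (7 + 1)
        assert result.last_day <= bound
        for r in result.requests:
            assert r.status in {"submitted", "declined", "escalated", "closed"}

    def test_deterministic_given_seed(self, request_factory):
        r1 = simulate_responses(request_factory(100), seed=7)
        r2 = simulate_responses(request_factory(100), seed=7)
        assert [(r.gene_id, r.status) for r in r1.requests] == \
            [(r.gene_id, r.status) for r in r2.requests]
        assert len(r1.snapshots) == len(r2.snapshots)

    def test_one_reminder_policy_skips_second_reminder(self, request_factory):
        policy = CampaignPolicy(max_reminders=1)
        result = simulate_responses(request_factory(60), (0.2, 0.2, 0.3), seed=5,
                                    policy=policy)
        table = summarize_campaign(result.requests).set_index("stage")
        assert table.loc["second_reminder", "n_emailed"] == 0
        assert table.loc["second_reminder", "percent"] is None
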
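"""Solicitation-campaign planning, state machine and reporting.

Each (gene, author) ask is a :class:`SolicitationRequest` moving through a
small state machine:

    pending ──deadline──▶ reminded_once ──deadline──▶ reminded_twice
       │                      │                            │
       │ (policy allows one reminder: escalate instead)    │
       ▼                      ▼                            ▼
    submitted / declined / bounced ◀──── responses ───▶ escalated

Authors asked for at most five genes receive individual e-mails with a
one-week reply deadline; authors asked for six or more receive a single
e-mail with a spreadsheet manifest and a four-week deadline.  Reminders are
due one full deadline period after the previous contact.  When a request is
exhausted (deadline passed after the last allowed reminder, or it bounced)
it escalates to the gene's next-ranked expert.  ``summarize_campaign``
tabulates, per stage, how many requests were active and how many snapshots
that stage yielded.
"""

from __future__ import annotations

import datetime as _dt
import string
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import CampaignPolicy
from .corpus import Author, Corpus, Gene, Snapshot
from .expert_rank import Assignment

__all__ = ["Action", "Batch", "Response", "SolicitationRequest", "TemplateError",
           "build_batches", "render_email", "next_action", "apply_action",
           "record_response", "summarize_campaign", "unique_snapshots",
           "percent", "stage_table", "STAGES", "TERMINAL_STATUSES"]

STAGES = ("initial", "first_reminder", "second_reminder", "second_author")
TERMINAL_STATUSES = frozenset({"submitted", "declined", "escalated", "closed"})

RESPONSE_KINDS = ("snapshot", "decline", "not_my_gene", "too_busy", "bounce")


class Action(Enum):
    WAIT = "wait"
    FIRST_REMINDER = "first_reminder"
    SECOND_REMINDER = "second_reminder"
    ESCALATE = "escalate"
    NONE = "none"


class TemplateError(ValueError):
    """The message template used a placeholder the renderer does not know."""


@dataclass
class SolicitationRequest:
    gene_id: str
    author_id: str
    batch_kind: str  # individual | spreadsheet
    sent_date: _dt.date
    deadline_days: int  # 7 for individual, 28 for spreadsheet
    status: str = "pending"
    history: list[tuple[str, str]] = field(default_factory=list)  # (iso date, event)
    author_rank: int = 0  # 0 = first-ranked expert, 1 = second, ...
    deadline_override: Optional[int] = None  # per-request custom deadline
    last_contact: Optional[_dt.date] = None
    submitted_stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.batch_kind not in ("individual", "spreadsheet"):
            raise ValueError(f"bad batch_kind {self.batch_kind!r}")
        if self.last_contact is None:
            self.last_contact = self.sent_date
        if not self.history:
            self.log(self.sent_date, "sent")

    @property
    def period(self) -> _dt.timedelta:
        return _dt.timedelta(days=self.deadline_override or self.deadline_days)

    @property
    def stage(self) -> str:
        """Which campaign stage this request is currently waiting in."""
        if self.author_rank >= 1:
            return "second_author"
        return {
            "pending": "initial",
            "reminded_once": "first_reminder",
            "reminded_twice": "second_reminder",
        }.get(self.status, "initial")

    def log(self, date: _dt.date, event: str) -> None:
        self.history.append((date.isoformat(), event))


@dataclass(frozen=True)
class Response:
    gene_id: str
    author_id: str
    kind: str
    date: _dt.date
    text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in RESPONSE_KINDS:
            raise ValueError(f"bad response kind {self.kind!r}")
        if self.kind == "snapshot" and not self.text:
            raise ValueError("snapshot responses must carry text")


@dataclass
class Batch:
    """One author's message plan: n individual mails, or one spreadsheet mail."""

    author_id: str
    kind: str  # individual | spreadsheet
    requests: list[SolicitationRequest]
    manifest: Optional[pd.DataFrame] = None  # spreadsheet batches only


def build_batches(
    assignments: Mapping[str, Assignment],
    corpus: Corpus,
    sent_date: _dt.date,
    policy: CampaignPolicy | None = None,
) -> list[Batch]:
    """Turn gene→author assignments into per-author message plans.

    Authors asked for ≤``individual_batch_limit`` genes get one individual
    request per gene (short deadline); authors over the limit get a single
    spreadsheet batch covering all their genes (long deadline) with a
    fill-in manifest of columns gene_id, symbol, name, snapshot_text.
    """
    pol = policy or CampaignPolicy()
    by_author: dict[str, list[Assignment]] = {}
    for gid in sorted(assignments):
        a = assignments[gid]
        if a.current_author is not None:
            by_author.setdefault(a.current_author, []).append(a)

    batches: list[Batch] = []
    for author_id in sorted(by_author):
        held = by_author[author_id]
        if len(held) <= pol.individual_batch_limit:
            kind, deadline = "individual", pol.individual_deadline_days
        else:
            kind, deadline = "spreadsheet", pol.spreadsheet_deadline_days
        requests = [
            SolicitationRequest(
                gene_id=a.gene_id, author_id=author_id, batch_kind=kind,
                sent_date=sent_date, deadline_days=deadline,
                author_rank=a.current_index,
            )
            for a in held
        ]
        manifest = None
        if kind == "spreadsheet":
            manifest = pd.DataFrame(
                [
                    {
                        "gene_id": a.gene_id,
                        "symbol": corpus.genes[a.gene_id].symbol,
                        "name": corpus.genes[a.gene_id].name,
                        "snapshot_text": "",
                    }
                    for a in held
                ]
            )
        batches.append(Batch(author_id, kind, requests, manifest))
    return batches


_OMISSION_LINES = {
    "gene_group_summary": "(no FlyBase gene group summary is available for this gene)",
    "interactive_fly_summary": "(no Interactive Fly summary is available for this gene)",
}


def render_email(
    request: SolicitationRequest,
    gene: Gene,
    author: Author,
    template: str,
    form_link: Optional[str] = None,
) -> str:
    """Fill the merge fields of *template*.

    Known placeholders: ``{surname}``, ``{symbol}``, ``{name}``,
    ``{gene_id}``, ``{form_link}``, ``{deadline_days}``,
    ``{gene_group_summary}``, ``{interactive_fly_summary}``.  Optional
    summaries that the gene lacks render as a documented omission line.
    An unknown placeholder raises :class:`TemplateError` naming it.
    """
    values = {
        "surname": author.surname,
        "symbol": gene.symbol,
        "name": gene.name,
        "gene_id": gene.gene_id,
        "form_link": form_link
        or f"https://forms.invalid/snapshot/{gene.gene_id}/{author.author_id}",
        "deadline_days": str(request.deadline_override or request.deadline_days),
        "gene_group_summary": gene.gene_group_summary
        or _OMISSION_LINES["gene_group_summary"],
        "interactive_fly_summary": gene.interactive_fly_summary
        or _OMISSION_LINES["interactive_fly_summary"],
    }
    for _, fname, _, _ in string.Formatter().parse(template):
        if fname is not None and fname not in values:
            raise TemplateError(f"unknown placeholder {fname!r} in template")
    return template.format(**values)


def next_action(
    request: SolicitationRequest,
    today: _dt.date,
    policy: CampaignPolicy | None = None,
) -> Action:
    """What the campaign should do with *request* on *today*.

    Deadlines are strict: a reminder becomes due the day after one full
    period has elapsed since the last contact.
    """
    pol = policy or CampaignPolicy()
    if request.status in TERMINAL_STATUSES:
        return Action.NONE
    if request.status == "bounced":
        return Action.ESCALATE
    due = request.last_contact + request.period
    if today <= due:
        return Action.WAIT
    if request.status == "pending":
        return Action.FIRST_REMINDER
    if request.status == "reminded_once":
        return Action.SECOND_REMINDER if pol.max_reminders >= 2 else Action.ESCALATE
    if request.status == "reminded_twice":
        return Action.ESCALATE
    raise ValueError(f"unknown status {request.status!r}")


def apply_action(request: SolicitationRequest, action: Action, today: _dt.date) -> None:
    """Perform *action*: send a reminder or mark the request escalated."""
    if action in (Action.WAIT, Action.NONE):
        return
    if action is Action.FIRST_REMINDER:
        request.status = "reminded_once"
        request.log(today, "first_reminder")
        request.last_contact = today
    elif action is Action.SECOND_REMINDER:
        request.status = "reminded_twice"
        request.log(today, "second_reminder")
        request.last_contact = today
    elif action is Action.ESCALATE:
        request.status = "escalated"
        request.log(today, "escalated")


def record_response(
    request: SolicitationRequest,
    response: Response,
    contributor: Optional[str] = None,
) -> Optional[Snapshot]:
    """Ingest a response; returns the Snapshot when one was submitted.

    A snapshot marks the request submitted (and remembers which stage the
    submission arrived in, for reporting); declines of any flavor mark it
    declined; a bounce marks it bounced (immediately escalatable).  Responses
    arriving after a terminal status only append to the history — duplicate
    submissions are kept, they are deduplicated at snapshot level.
    """
    if (response.gene_id, response.author_id) != (request.gene_id, request.author_id):
        raise ValueError(
            f"response for ({response.gene_id}, {response.author_id}) does not "
            f"match request ({request.gene_id}, {request.author_id})"
        )
    request.log(response.date, f"response:{response.kind}")
    snapshot: Optional[Snapshot] = None
    if response.kind == "snapshot":
        snapshot = Snapshot(
            gene_id=request.gene_id,
            text=response.text,
            contributor=contributor or request.author_id,
            date_stamp=response.date.isoformat(),
        )
    if request.status in TERMINAL_STATUSES:
        return snapshot
    if response.kind == "snapshot":
        request.submitted_stage = request.stage
        request.status = "submitted"
    elif response.kind == "bounce":
        request.status = "bounced"
    else:
        request.status = "declined"
    return snapshot


def percent(numerator: int, denominator: int) -> Optional[int]:
    """Whole-percent share, half rounded up; None when nothing was e-mailed."""
    if denominator == 0:
        return None
    import math

    return int(math.floor(100.0 * numerator / denominator + 0.5))


def stage_table(rows: Sequence[tuple[str, int, int]]) -> pd.DataFrame:
    """Build the stage report from (stage, n_emailed, n_received) triples."""
    df = pd.DataFrame(
        [{"stage": stage, "n_emailed": den, "n_received": num}
         for stage, den, num in rows]
    )
    # object dtype so an all-int column can still hold None (not-applicable)
    df["percent"] = pd.Series([percent(num, den) for _, den, num in rows],
                              dtype="object")
    return df


def summarize_campaign(requests: Iterable[SolicitationRequest]) -> pd.DataFrame:
    """Stage-wise response table: how many requests entered each stage and
    how many snapshots that stage produced.

    Stages for first-ranked authors are initial contact, first reminder and
    second reminder; everything asked of lower-ranked authors after an
    escalation is pooled into the second-author stage.  Denominators count
    requests that were actually contacted at the stage; original bookkeeping
    around manual removals may make published denominators differ.
    """
    reqs = list(requests)
    first = [r for r in reqs if r.author_rank == 0]
    later = [r for r in reqs if r.author_rank >= 1]
    events = lambda r: {e for _, e in r.history}
    rows = [
        ("initial", len(first),
         sum(r.submitted_stage == "initial" for r in first)),
        ("first_reminder",
         sum("first_reminder" in events(r) for r in first),
         sum(r.submitted_stage == "first_reminder" for r in first)),
        ("second_reminder",
         sum("second_reminder" in events(r) for r in first),
         sum(r.submitted_stage == "second_reminder" for r in first)),
        ("second_author", len(later),
         sum(r.status == "submitted" for r in later)),
    ]
    return stage_table(rows)


DEFAULT_TEMPLATE = """\
Dear Dr {surname},

We are writing to ask whether you could draft a brief summary (a "gene
snapshot") of the main function(s) of the product of {symbol} ({name},
{gene_id}) — a couple of sentences or bullet points on how the protein
functions, what pathway it is in (if relevant) and its main biological
roles, for a general, non-specialist audience.

To help, here is the information already on file:
  Gene group: {gene_group_summary}
  Interactive Fly: {interactive_fly_summary}

Please reply within {deadline_days} days using this form:
  {form_link}

With many thanks,
the curation team
"""


_REQUEST_COLUMNS = ["gene_id", "author_id", "batch_kind", "sent_date",
                    "deadline_days", "status", "author_rank",
                    "deadline_override", "last_contact", "submitted_stage",
                    "history"]


def save_requests(requests: Sequence[SolicitationRequest], path) -> None:
    """Persist the campaign ledger as TSV (history as ``date=event;...``)."""
    rows = []
    for r in requests:
        rows.append({
            "gene_id": r.gene_id, "author_id": r.author_id,
            "batch_kind": r.batch_kind, "sent_date": r.sent_date.isoformat(),
            "deadline_days": r.deadline_days, "status": r.status,
            "author_rank": r.author_rank,
            "deadline_override": r.deadline_override if r.deadline_override else "",
            "last_contact": r.last_contact.isoformat(),
            "submitted_stage": r.submitted_stage or "",
            "history": ";".join(f"{d}={e}" for d, e in r.history),
        })
    pd.DataFrame(rows, columns=_REQUEST_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def load_requests(path) -> list[SolicitationRequest]:
    """Inverse of :func:`save_requests`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[SolicitationRequest] = []
    for row in df.itertuples(index=False):
        history = [tuple(item.split("=", 1)) for item in row.history.split(";") if item]
        req = SolicitationRequest(
            gene_id=row.gene_id, author_id=row.author_id,
            batch_kind=row.batch_kind,
            sent_date=_dt.date.fromisoformat(row.sent_date),
            deadline_days=int(row.deadline_days), status=row.status,
            history=history, author_rank=int(row.author_rank),
            deadline_override=int(row.deadline_override) if row.deadline_override else None,
            last_contact=_dt.date.fromisoformat(row.last_contact),
            submitted_stage=row.submitted_stage or None,
        )
        out.append(req)
    return out


def unique_snapshots(snapshots: Iterable[Snapshot]) -> list[Snapshot]:
    """One snapshot per gene, keeping the earliest submission (first seen on
    equal dates); overlapping unsolicited duplicates are dropped."""
    best: dict[str, Snapshot] = {}
    for snap in snapshots:
        kept = best.get(snap.gene_id)
        if kept is None or snap.date_stamp < kept.date_stamp:
            best[snap.gene_id] = snap
    return list(best.values())
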
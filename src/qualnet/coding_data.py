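"""Data model and I/O for coded qualitative interview data.

The central objects are a :class:`Codebook` of hierarchically numbered codes
grouped into themes, an interviewee roster split into patients and experts
(the expert group further split into clinicians/health-system experts and
basic scientists), and a long-format :class:`ResponseTable` recording which
interviewee addressed which code, optionally with a yes/no concern label per
response.  From the responses a binary code x interviewee incidence matrix B
is built: ``b_ij = 1`` iff interviewee j responded to code i.  Multiple coded
phrases by one interviewee for one code collapse to a single binary link.

The module also packages a marginal-level fixture: the published per-code
patient/expert response counts of a 16-interviewee, 43-code corpus on
personalized oncological medicine (7 themes).  The individual-level incidence
behind it is unpublished, so the fixture carries marginals only; demonstration
networks are synthesized to match them (see :mod:`qualnet.synthetic`).

All delimited files are comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "Subgroup",
    "ConcernLabel",
    "Codebook",
    "Interviewee",
    "ResponseRecord",
    "ResponseTable",
    "IncidenceMatrix",
    "MarginalSummary",
    "load_codebook",
    "load_roster",
    "load_responses",
    "build_incidence",
    "marginal_summary",
    "table1_fixture",
    "table1_roster",
    "write_codebook",
    "write_roster",
    "write_responses",
    "write_incidence",
    "read_incidence",
    "round_half_away",
]


class Role(str, Enum):
    patient = "patient"
    expert = "expert"


class Subgroup(str, Enum):
    clinician_health_system = "clinician_health_system"
    basic_scientist = "basic_scientist"
    none = "none"


class ConcernLabel(str, Enum):
    """Per-response dichotomization of the key statement.

    ``yes`` is the concern-present (negatively connoted) outcome; ``no`` means
    the response explicitly voiced no concern; ``unclassifiable`` means a
    key statement exists but cannot be dichotomized; ``absent`` means the
    input carried no dichotomization at all.
    """

    yes = "yes"
    no = "no"
    unclassifiable = "unclassifiable"
    absent = "absent"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass(frozen=True)
class Codebook:
    """Ordered themes and codes; ``code_id`` is ``"<theme_id>.<k>"``."""

    themes: tuple[tuple[str, str], ...]  # (theme_id, label)
    codes: tuple[tuple[str, str, str], ...]  # (code_id, theme_id, label)

    def __post_init__(self) -> None:
        if not self.themes:
            raise ValidationError("codebook must contain at least one theme")
        theme_ids = [t for t, _ in self.themes]
        if len(set(theme_ids)) != len(theme_ids):
            raise ValidationError("duplicate theme_id in codebook")
        code_ids = [c for c, _, _ in self.codes]
        if len(set(code_ids)) != len(code_ids):
            raise ValidationError("duplicate code_id in codebook")
        known = set(theme_ids)
        for code_id, theme_id, _ in self.codes:
            if theme_id not in known:
                raise ValidationError(
                    f"code {code_id!r} references unknown theme {theme_id!r}"
                )
            if not code_id.startswith(theme_id + "."):
                raise ValidationError(
                    f"code_id {code_id!r} is not prefixed by its theme_id {theme_id!r}"
                )

    @property
    def code_ids(self) -> list[str]:
        return [c for c, _, _ in self.codes]

    @property
    def theme_ids(self) -> list[str]:
        return [t for t, _ in self.themes]

    def theme_of(self, code_id: str) -> str:
        for cid, tid, _ in self.codes:
            if cid == code_id:
                return tid
        raise ValidationError(f"unknown code_id {code_id!r}")

    def codes_of_theme(self, theme_id: str) -> list[str]:
        return [c for c, t, _ in self.codes if t == theme_id]


@dataclass(frozen=True)
class Interviewee:
    interviewee_id: str
    role: Role
    subgroup: Subgroup = Subgroup.none

    def __post_init__(self) -> None:
        if (self.subgroup is Subgroup.none) != (self.role is Role.patient):
            raise ValidationError(
                f"interviewee {self.interviewee_id!r}: subgroup must be 'none' "
                "iff role is 'patient'"
            )


@dataclass(frozen=True)
class ResponseRecord:
    interviewee_id: str
    code_id: str
    concern_label: ConcernLabel = ConcernLabel.absent


@dataclass(frozen=True)
class ResponseTable:
    records: tuple[ResponseRecord, ...]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary M x N matrix B: rows are codes, columns are interviewees."""

    B: np.ndarray
    code_index: tuple[str, ...]
    interviewee_index: tuple[str, ...]

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=int)
        if B.ndim != 2:
            raise ValidationError("incidence matrix must be two-dimensional")
        if B.shape != (len(self.code_index), len(self.interviewee_index)):
            raise ValidationError("incidence shape disagrees with its index labels")
        if not np.isin(B, (0, 1)).all():
            raise ValidationError("incidence entries must be exactly 0 or 1")
        object.__setattr__(self, "B", B)

    @property
    def M(self) -> int:
        return len(self.code_index)

    @property
    def N(self) -> int:
        return len(self.interviewee_index)

    @property
    def num_links(self) -> int:
        return int(self.B.sum())


@dataclass(frozen=True)
class MarginalSummary:
    """Per-code and per-theme response counts split by interviewee role."""

    per_code: Mapping[str, tuple[int, int]]  # code_id -> (patients, experts)
    per_theme: Mapping[str, tuple[int, int]]
    total_links: int

    def code_total(self, code_id: str) -> int:
        p, e = self.per_code[code_id]
        return p + e


# ---------------------------------------------------------------------------
# loaders


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_codebook(path) -> Codebook:
    """Load a codebook CSV with columns theme_id, code_id, label.

    Theme labels may be supplied in an optional ``theme_label`` column
    (first occurrence wins); otherwise themes are labelled by their id.
    File order is preserved for both themes and codes.
    """
    df = _read_csv(path, ["theme_id", "code_id", "label"])
    themes: list[tuple[str, str]] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        tid = row["theme_id"]
        if tid not in seen:
            seen.add(tid)
            themes.append((tid, row.get("theme_label", tid) or tid))
    codes = tuple(
        (row["code_id"], row["theme_id"], row["label"]) for _, row in df.iterrows()
    )
    return Codebook(themes=tuple(themes), codes=codes)


def load_roster(path) -> list[Interviewee]:
    """Load the interviewee roster CSV (interviewee_id, role, subgroup)."""
    df = _read_csv(path, ["interviewee_id", "role"])
    roster: list[Interviewee] = []
    for _, row in df.iterrows():
        try:
            role = Role(row["role"])
            sub = Subgroup(row.get("subgroup", "") or "none")
        except ValueError as exc:
            raise ValidationError(f"roster row {row.to_dict()}: {exc}") from exc
        roster.append(Interviewee(row["interviewee_id"], role, sub))
    ids = [iv.interviewee_id for iv in roster]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate interviewee_id in roster")
    return roster


def load_responses(path, codebook: Codebook, roster: Sequence[Interviewee]) -> ResponseTable:
    """Load long-format responses; collapse exact duplicates, reject conflicts.

    Duplicate (interviewee, code) rows with the same concern label collapse to
    one record (one warning per collapse); duplicates with conflicting labels
    are an error — each response carries a single key statement, so conflicts
    must be resolved upstream.
    """
    df = _read_csv(path, ["interviewee_id", "code_id"])
    known_codes = set(codebook.code_ids)
    known_ivs = {iv.interviewee_id for iv in roster}
    out: dict[tuple[str, str], ConcernLabel] = {}
    order: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        iid, cid = row["interviewee_id"], row["code_id"]
        if iid not in known_ivs:
            raise ValidationError(f"unknown interviewee_id {iid!r} in responses")
        if cid not in known_codes:
            raise ValidationError(f"unknown code_id {cid!r} in responses")
        raw = row.get("concern_label", "") or "absent"
        try:
            label = ConcernLabel(raw)
        except ValueError as exc:
            raise ValidationError(f"bad concern_label {raw!r} for ({iid}, {cid})") from exc
        key = (iid, cid)
        if key in out:
            if out[key] is not label:
                raise ValidationError(
                    f"conflicting concern labels for ({iid}, {cid}): "
                    f"{out[key].value!r} vs {label.value!r}"
                )
            logger.warning("collapsing duplicate response (%s, %s)", iid, cid)
        else:
            out[key] = label
            order.append(key)
    return ResponseTable(
        records=tuple(ResponseRecord(i, c, out[(i, c)]) for i, c in order)
    )


# ---------------------------------------------------------------------------
# incidence and marginals


def build_incidence(
    responses: ResponseTable, codebook: Codebook, roster: Sequence[Interviewee]
) -> IncidenceMatrix:
    """Build the binary incidence matrix B from a response table.

    Codes keep codebook order as rows; interviewees keep roster order as
    columns.  Codes or interviewees with zero responses still occupy a
    row/column.
    """
    code_index = tuple(codebook.code_ids)
    iv_index = tuple(iv.interviewee_id for iv in roster)
    row = {c: i for i, c in enumerate(code_index)}
    col = {v: j for j, v in enumerate(iv_index)}
    B = np.zeros((len(code_index), len(iv_index)), dtype=int)
    for rec in responses.records:
        B[row[rec.code_id], col[rec.interviewee_id]] = 1
    return IncidenceMatrix(B=B, code_index=code_index, interviewee_index=iv_index)


def marginal_summary(
    incidence: IncidenceMatrix,
    roster: Sequence[Interviewee],
    codebook: Codebook,
) -> MarginalSummary:
    """Per-code and per-theme response counts split by patient/expert role."""
    roles = {iv.interviewee_id: iv.role for iv in roster}
    is_patient = np.array(
        [roles[v] is Role.patient for v in incidence.interviewee_index]
    )
    per_code: dict[str, tuple[int, int]] = {}
    for i, cid in enumerate(incidence.code_index):
        row = incidence.B[i]
        per_code[cid] = (int(row[is_patient].sum()), int(row[~is_patient].sum()))
    per_theme: dict[str, tuple[int, int]] = {}
    for tid in codebook.theme_ids:
        members = [c for c in codebook.codes_of_theme(tid) if c in per_code]
        per_theme[tid] = (
            sum(per_code[c][0] for c in members),
            sum(per_code[c][1] for c in members),
        )
    return MarginalSummary(
        per_code=per_code, per_theme=per_theme, total_links=incidence.num_links
    )


# ---------------------------------------------------------------------------
# packaged fixture


def _data_path(name: str):
    return resources.files("qualnet.data").joinpath(name)


def table1_fixture() -> tuple[Codebook, MarginalSummary]:
    """The packaged 7-theme / 43-code codebook with published marginals.

    Returns the codebook together with the per-code (patient, expert)
    response counts, per-theme totals, and the grand total of links.  These
    are corpus-level marginals; the interviewee-level incidence is not public.
    """
    tdf = pd.read_csv(_data_path("table1_themes.csv"), dtype=str)
    cdf = pd.read_csv(
        _data_path("table1_codes.csv"),
        dtype={"theme_id": str, "code_id": str, "label": str},
    )
    codebook = Codebook(
        themes=tuple(zip(tdf["theme_id"], tdf["label"])),
        codes=tuple(zip(cdf["code_id"], cdf["theme_id"], cdf["label"])),
    )
    per_code = {
        row.code_id: (int(row.patient_count), int(row.expert_count))
        for row in cdf.itertuples()
    }
    per_theme = {
        tid: (
            sum(per_code[c][0] for c in codebook.codes_of_theme(tid)),
            sum(per_code[c][1] for c in codebook.codes_of_theme(tid)),
        )
        for tid in codebook.theme_ids
    }
    total = sum(p + e for p, e in per_code.values())
    return codebook, MarginalSummary(per_code, per_theme, total)


def table1_roster() -> list[Interviewee]:
    """Roster matching the fixture corpus: 2 patients, 10 clinician/health-system
    experts, 4 basic scientists.  Which named expert belongs to which subgroup
    is not public; the split sizes are."""
    roster = [Interviewee(f"P_{i}", Role.patient) for i in (1, 2)]
    roster += [
        Interviewee(f"E_{i}", Role.expert, Subgroup.clinician_health_system)
        for i in range(1, 11)
    ]
    roster += [
        Interviewee(f"E_{i}", Role.expert, Subgroup.basic_scientist)
        for i in range(11, 15)
    ]
    return roster


# ---------------------------------------------------------------------------
# writers and the incidence round trip


def write_codebook(codebook: Codebook, path) -> None:
    theme_label = dict(codebook.themes)
    pd.DataFrame(
        [
            {
                "theme_id": tid,
                "code_id": cid,
                "label": label,
                "theme_label": theme_label[tid],
            }
            for cid, tid, label in codebook.codes
        ]
    ).to_csv(path, index=False)


def write_roster(roster: Iterable[Interviewee], path) -> None:
    pd.DataFrame(
        [
            {
                "interviewee_id": iv.interviewee_id,
                "role": iv.role.value,
                "subgroup": iv.subgroup.value,
            }
            for iv in roster
        ]
    ).to_csv(path, index=False)


def write_responses(responses: ResponseTable, path) -> None:
    pd.DataFrame(
        [
            {
                "interviewee_id": r.interviewee_id,
                "code_id": r.code_id,
                "concern_label": r.concern_label.value,
            }
            for r in responses.records
        ],
        columns=["interviewee_id", "code_id", "concern_label"],
    ).to_csv(path, index=False)


def write_incidence(incidence: IncidenceMatrix, path) -> None:
    """Write B as CSV with code_id row labels and interviewee_id columns."""
    df = pd.DataFrame(
        incidence.B,
        index=list(incidence.code_index),
        columns=list(incidence.interviewee_index),
    )
    df.to_csv(path, index_label="code_id")


def read_incidence(path) -> IncidenceMatrix:
    """Read an incidence CSV; bit-exact inverse of :func:`write_incidence`."""
    try:
        df = pd.read_csv(path, index_col="code_id")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty incidence matrix rejected")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: incidence entries must be 0 or 1")
    return IncidenceMatrix(
        B=values.astype(int),
        code_index=tuple(str(c) for c in df.index),
        interviewee_index=tuple(str(c) for c in df.columns),
    )
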
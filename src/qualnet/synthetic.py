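"""Seeded synthetic coded-interview datasets.

The raw interviewee-level data behind the studied corpus are not public, so
this module generates datasets with the statistical structure the analysis
assumes: binary interviewee x code incidence with role/subgroup- and
theme-dependent response probabilities, optional planted bicliques, and
per-response yes/no concern labels.

Defaults emulate the studied corpus: 2 patients, 10 clinician/health-system
experts and 4 basic scientists over 7 themes of sizes (7, 9, 5, 4, 5, 5, 8) —
43 codes by 16 interviewees.  The default uniform response probability 0.32
matches the corpus density (220 links / 688 cells); the default yes-fraction
0.7 and unclassifiable rate 0.14 match the packaged concern reconstruction.

Two fixture-flavoured generators draw datasets pinned to the published
marginals: :func:`table1_consistent_incidence` (row sums split by role match
the published per-code counts exactly; the within-role column assignment is
uniform at random because the true assignment is unpublished, so
interviewee-level degrees are NOT reproduced) and
:func:`table1_synthetic_responses` (additionally realises the packaged
synthetic concern splits as per-response labels).

All randomness flows from one explicit numpy Generator per call; identical
seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coding_data import (
    Codebook,
    ConcernLabel,
    IncidenceMatrix,
    Interviewee,
    ResponseRecord,
    ResponseTable,
    Role,
    Subgroup,
    build_incidence,
    table1_fixture,
    table1_roster,
)
from .errors import ValidationError

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "plant_biclique",
    "table1_consistent_incidence",
    "table1_synthetic_responses",
    "synthetic_concern_splits",
]

CORPUS_THEME_SIZES = (7, 9, 5, 4, 5, 5, 8)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    ``response_prob`` maps (group, theme_id) to a link probability, where the
    group key may be a subgroup ("clinician_health_system",
    "basic_scientist"), a role ("patient", "expert") or the wildcard "*", and
    the theme key may be a theme id or "*".  Lookup prefers the most specific
    match (subgroup over role over wildcard; exact theme over wildcard).
    ``concern_prob`` maps a code_id (or "*") to the probability that a
    classifiable response is "yes"; ``unclassifiable_prob`` is the chance a
    response carries no usable key statement at all.
    """

    n_patients: int = 2
    n_clinician_experts: int = 10
    n_basic_scientists: int = 4
    theme_sizes: tuple[int, ...] = CORPUS_THEME_SIZES
    response_prob: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("*", "*"): 0.32}
    )
    concern_prob: Mapping[str, float] = field(default_factory=lambda: {"*": 0.7})
    unclassifiable_prob: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_clinician_experts, self.n_basic_scientists) < 0:
            raise ValidationError("group sizes must be non-negative")
        n_iv = self.n_patients + self.n_clinician_experts + self.n_basic_scientists
        if n_iv < 1 or sum(self.theme_sizes) < 1:
            raise ValidationError("need at least one interviewee and one code")
        if any(s < 0 for s in self.theme_sizes):
            raise ValidationError("theme sizes must be non-negative")
        probs = [*self.response_prob.values(), *self.concern_prob.values(),
                 self.unclassifiable_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")

    def lookup_response_prob(self, interviewee: Interviewee, theme_id: str) -> float:
        keys = []
        if interviewee.subgroup is not Subgroup.none:
            keys += [(interviewee.subgroup.value, theme_id),
                     (interviewee.role.value, theme_id),
                     (interviewee.subgroup.value, "*")]
        else:
            keys += [(interviewee.role.value, theme_id)]
        keys += [(interviewee.role.value, "*"), ("*", theme_id), ("*", "*")]
        for key in keys:
            if key in self.response_prob:
                return float(self.response_prob[key])
        return 0.0

    def lookup_concern_prob(self, code_id: str) -> float:
        return float(self.concern_prob.get(code_id, self.concern_prob.get("*", 0.5)))


@dataclass(frozen=True)
class SyntheticDataset:
    codebook: Codebook
    roster: tuple[Interviewee, ...]
    responses: ResponseTable
    truth: dict

    def incidence(self) -> IncidenceMatrix:
        return build_incidence(self.responses, self.codebook, self.roster)


def _make_codebook(theme_sizes: Iterable[int]) -> Codebook:
    themes, codes = [], []
    for t, size in enumerate(theme_sizes, start=1):
        themes.append((str(t), f"Theme {t}"))
        for k in range(1, size + 1):
            codes.append((f"{t}.{k}", str(t), f"Code {t}.{k}"))
    return Codebook(themes=tuple(themes), codes=tuple(codes))


def _make_roster(cfg: GeneratorConfig) -> tuple[Interviewee, ...]:
    roster = [Interviewee(f"P_{i}", Role.patient) for i in range(1, cfg.n_patients + 1)]
    roster += [
        Interviewee(f"E_{i}", Role.expert, Subgroup.clinician_health_system)
        for i in range(1, cfg.n_clinician_experts + 1)
    ]
    roster += [
        Interviewee(f"E_{i}", Role.expert, Subgroup.basic_scientist)
        for i in range(
            cfg.n_clinician_experts + 1,
            cfg.n_clinician_experts + cfg.n_basic_scientists + 1,
        )
    ]
    return tuple(roster)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset.

    Each (interviewee, code) link is an independent Bernoulli with the
    group-by-theme probability.  Per link, the response is unclassifiable
    with ``unclassifiable_prob``; otherwise "yes" with the code's concern
    probability, else "no".
    """
    rng = np.random.default_rng(config.seed)
    codebook = _make_codebook(config.theme_sizes)
    roster = _make_roster(config)
    records: list[ResponseRecord] = []
    for code_id, theme_id, _ in codebook.codes:
        c_prob = config.lookup_concern_prob(code_id)
        for iv in roster:
            if rng.random() < config.lookup_response_prob(iv, theme_id):
                if rng.random() < config.unclassifiable_prob:
                    label = ConcernLabel.unclassifiable
                elif rng.random() < c_prob:
                    label = ConcernLabel.yes
                else:
                    label = ConcernLabel.no
                records.append(ResponseRecord(iv.interviewee_id, code_id, label))
    return SyntheticDataset(
        codebook=codebook,
        roster=roster,
        responses=ResponseTable(records=tuple(records)),
        truth={"config": config, "planted_bicliques": []},
    )


def plant_biclique(
    dataset: SyntheticDataset,
    code_ids: Iterable[str],
    interviewee_ids: Iterable[str],
) -> SyntheticDataset:
    """Force every (code, interviewee) cross pair present; record in truth.

    Newly created links carry no concern annotation (label ``absent``).
    """
    code_ids = frozenset(code_ids)
    interviewee_ids = frozenset(interviewee_ids)
    if not code_ids or not interviewee_ids:
        raise ValidationError("planted biclique sides must be non-empty")
    known_codes = set(dataset.codebook.code_ids)
    known_ivs = {iv.interviewee_id for iv in dataset.roster}
    if not code_ids <= known_codes:
        raise ValidationError(f"unknown code ids: {sorted(code_ids - known_codes)}")
    if not interviewee_ids <= known_ivs:
        raise ValidationError(
            f"unknown interviewee ids: {sorted(interviewee_ids - known_ivs)}"
        )
    present = {(r.interviewee_id, r.code_id) for r in dataset.responses.records}
    new = [
        ResponseRecord(iid, cid)
        for cid in sorted(code_ids)
        for iid in sorted(interviewee_ids)
        if (iid, cid) not in present
    ]
    truth = dict(dataset.truth)
    truth["planted_bicliques"] = list(truth.get("planted_bicliques", [])) + [
        (code_ids, interviewee_ids)
    ]
    return replace(
        dataset,
        responses=ResponseTable(records=dataset.responses.records + tuple(new)),
        truth=truth,
    )


def table1_consistent_incidence(seed: int) -> IncidenceMatrix:
    """Random 43 x 16 incidence whose per-code patient/expert counts equal the
    packaged marginals exactly.

    Per code, the patient links are assigned uniformly without replacement
    among the 2 patient columns and the expert links among the 14 expert
    columns.  Row sums are therefore guaranteed; column (interviewee) degrees
    are random.
    """
    rng = np.random.default_rng(seed)
    codebook, marginals = table1_fixture()
    roster = table1_roster()
    patients = [j for j, iv in enumerate(roster) if iv.role is Role.patient]
    experts = [j for j, iv in enumerate(roster) if iv.role is Role.expert]
    B = np.zeros((len(codebook.code_ids), len(roster)), dtype=int)
    for i, cid in enumerate(codebook.code_ids):
        p, e = marginals.per_code[cid]
        for j in rng.choice(patients, size=p, replace=False):
            B[i, j] = 1
        for j in rng.choice(experts, size=e, replace=False):
            B[i, j] = 1
    return IncidenceMatrix(
        B=B,
        code_index=tuple(codebook.code_ids),
        interviewee_index=tuple(iv.interviewee_id for iv in roster),
    )


def synthetic_concern_splits() -> dict[str, tuple[int, int]]:
    """The packaged synthetic per-code (yes, no) concern splits.

    A reconstruction, not original data: the full per-code dichotomization
    of the studied corpus is unpublished, so this table was built to agree
    with every published per-code split and with the published totals
    (28 dichotomizable codes, 22 excluded responses among them, and a
    5 / 11 / 12 no-concern / controversial / all-concern partition).
    """
    df = pd.read_csv(
        resources.files("qualnet.data").joinpath("concern_splits_synthetic.csv"),
        dtype={"code_id": str},
    )
    return {
        row.code_id: (int(row.yes_count), int(row.no_count)) for row in df.itertuples()
    }


def table1_synthetic_responses(
    seed: int,
) -> tuple[Codebook, tuple[Interviewee, ...], ResponseTable]:
    """A full synthetic response table pinned to the published marginals,
    with concern labels realising the packaged synthetic splits.

    For each code the responding interviewees come from
    :func:`table1_consistent_incidence`; among them, yes/no/unclassifiable
    labels are assigned in random order matching the split counts.  Codes
    outside the split table get only unclassifiable labels.
    """
    rng = np.random.default_rng(seed)
    incidence = table1_consistent_incidence(seed)
    codebook, _ = table1_fixture()
    roster = tuple(table1_roster())
    splits = synthetic_concern_splits()
    records: list[ResponseRecord] = []
    for i, cid in enumerate(incidence.code_index):
        responders = [
            incidence.interviewee_index[j]
            for j in np.nonzero(incidence.B[i])[0]
        ]
        responders = [responders[k] for k in rng.permutation(len(responders))]
        y, n = splits.get(cid, (0, 0))
        if y + n > len(responders):  # pragma: no cover - fixture guarantees room
            raise ValidationError(f"split for {cid} exceeds its response count")
        for pos, iid in enumerate(responders):
            if pos < y:
                label = ConcernLabel.yes
            elif pos < y + n:
                label = ConcernLabel.no
            else:
                label = ConcernLabel.unclassifiable
            records.append(ResponseRecord(iid, cid, label))
    return codebook, roster, ResponseTable(records=tuple(records))
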
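import itertools

import numpy as np
import pytest

import qualnet as qn


@pytest.fixture(scope="session")
def table1():
    """Packaged codebook + published per-code marginals."""
    return qn.table1_fixture()


@pytest.fixture(scope="session")
def roster16():
    return qn.table1_roster()


@pytest.fixture
def tiny_codebook():
    return qn.Codebook(
        themes=(("1", "Theme 1"), ("2", "Theme 2")),
        codes=(
            ("1.1", "1", "alpha"),
            ("1.2", "1", "beta"),
            ("2.1", "2", "gamma"),
        ),
    )


@pytest.fixture
def tiny_roster():
    return [
        qn.Interviewee("P_1", qn.Role.patient),
        qn.Interviewee("E_1", qn.Role.expert, qn.Subgroup.clinician_health_system),
        qn.Interviewee("E_2", qn.Role.expert, qn.Subgroup.basic_scientist),
    ]


def make_incidence(B, codes=None, ivs=None):
    B = np.asarray(B, dtype=int)
    M, N = B.shape
    return qn.IncidenceMatrix(
        B=B,
        code_index=tuple(codes or (f"c{i}" for i in range(M))),
        interviewee_index=tuple(ivs or (f"v{j}" for j in range(N))),
    )


def bruteforce_bicliques(B):
    """Independent maximal-biclique oracle by exhaustive subset enumeration.

    For every non-empty row (code) subset S, collect the columns linked to all
    of S; group candidates by that column set and take the union of the row
    subsets mapping to it (the largest row set complete against those
    columns).  The surviving pairs with both sides non-empty are exactly the
    maximal bicliques.
    """
    B = np.asarray(B, dtype=int)
    M, N = B.shape
    full = (1 << N) - 1
    row_mask = [int(sum(1 << j for j in range(N) if B[i, j])) for i in range(M)]
    by_cols: dict[int, int] = {}
    for r in range(1, M + 1):
        for S in itertools.combinations(range(M), r):
            cols = full
            for i in S:
                cols &= row_mask[i]
            if cols:
                smask = 0
                for i in S:
                    smask |= 1 << i
                by_cols[cols] = by_cols.get(cols, 0) | smask
    out = set()
    for cols, rows in by_cols.items():
        out.add(
            (
                frozenset(i for i in range(M) if rows >> i & 1),
                frozenset(j for j in range(N) if cols >> j & 1),
            )
        )
    return out


def check_complete_and_maximal(B, code_rows, iv_cols):
    """Independent completeness + maximality check for one biclique."""
    B = np.asarray(B, dtype=int)
    assert code_rows and iv_cols
    for i in code_rows:
        for j in iv_cols:
            assert B[i, j] == 1, "biclique not complete"
    for i in set(range(B.shape[0])) - set(code_rows):
        assert not all(B[i, j] for j in iv_cols), "extendable by a code row"
    for j in set(range(B.shape[1])) - set(iv_cols):
        assert not all(B[i, j] for i in code_rows), "extendable by an interviewee"


def as_index_pairs(bicliques, incidence):
    """Map Biclique objects to (row index set, column index set) pairs."""
    row = {c: i for i, c in enumerate(incidence.code_index)}
    col = {v: j for j, v in enumerate(incidence.interviewee_index)}
    return {
        (
            frozenset(row[c] for c in bc.code_set),
            frozenset(col[v] for v in bc.interviewee_set),
        )
        for bc in bicliques
    }
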
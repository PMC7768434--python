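#!/usr/bin/env python
"""Dichotomized concern multigraph and controversy partition.

Realises the packaged synthetic concern splits (a reconstruction consistent
with every published per-code split) as per-response labels, classifies them,
builds the weighted yes/no multigraph and writes its tables and a GEXF export
under results/.
"""

from pathlib import Path

import pandas as pd

import qualnet as qn

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 1


def main() -> None:
    cb, _, responses = qn.table1_synthetic_responses(SEED)
    cls = qn.classify_responses(responses)
    ci = qn.build_concern_incidence(cls, cb)
    mg = qn.build_concern_network(ci)
    rep = qn.controversy_report(ci)

    kept = {c for c, _ in cls.labels}
    dropped_in_kept = sum(
        1
        for r in responses.records
        if r.code_id in kept
        and r.concern_label not in (qn.ConcernLabel.yes, qn.ConcernLabel.no)
    )
    print(f"dichotomizable codes: {ci.M} of {len(cb.codes)} "
          f"({len(cls.excluded_codes)} codes excluded entirely)")
    print(f"responses excluded within dichotomizable codes: {dropped_in_kept}")
    print(f"partition: {len(rep.no_concern)} no-concern "
          f"({', '.join(sorted(rep.no_concern))}), "
          f"{len(rep.controversial)} controversial, "
          f"{len(rep.all_concern)} all-concern")
    print(f"total yes answers {int(ci.Bp[:, 0].sum())}, "
          f"no answers {int(ci.Bp[:, 1].sum())}")

    pd.DataFrame(
        {
            "code_id": list(ci.code_index),
            "yes_count": ci.Bp[:, 0],
            "no_count": ci.Bp[:, 1],
        }
    ).to_csv(OUT / "concern_incidence.csv", index=False)
    qn.export_concern_graph(mg, "gexf", OUT / "concern_network.gexf")
    print(f"wrote {OUT / 'concern_incidence.csv'} and concern_network.gexf")


if __name__ == "__main__":
    main()
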
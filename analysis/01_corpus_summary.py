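#!/usr/bin/env python
"""Corpus overview: themes, codes and patient/expert response marginals.

Loads the packaged published-marginal fixture (7 themes, 43 codes, 16
interviewees) and writes the per-code and per-theme response tables under
results/, printing the headline counts.
"""

from pathlib import Path

import pandas as pd

import qualnet as qn

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    cb, ms = qn.table1_fixture()
    theme_label = dict(cb.themes)
    rows = [
        {
            "code_id": cid,
            "theme_id": tid,
            "label": label,
            "patient_responses": ms.per_code[cid][0],
            "expert_responses": ms.per_code[cid][1],
        }
        for cid, tid, label in cb.codes
    ]
    pd.DataFrame(rows).to_csv(OUT / "corpus_per_code.csv", index=False)
    pd.DataFrame(
        [
            {
                "theme_id": tid,
                "label": theme_label[tid],
                "n_codes": len(cb.codes_of_theme(tid)),
                "patient_responses": ms.per_theme[tid][0],
                "expert_responses": ms.per_theme[tid][1],
            }
            for tid in cb.theme_ids
        ]
    ).to_csv(OUT / "corpus_per_theme.csv", index=False)

    sizes = [len(cb.codes_of_theme(t)) for t in cb.theme_ids]
    print(f"corpus: {len(cb.themes)} themes, {len(cb.codes)} codes, "
          f"{ms.total_links} responses (links)")
    print(f"theme sizes: {sizes} -> largest theme 2 ({max(sizes)} codes), "
          f"smallest theme 4 ({min(sizes)} codes), "
          f"mean {qn.round_half_away(len(cb.codes) / len(cb.themes))}")
    expert = {t: e for t, (_, e) in ms.per_theme.items()}
    top = max(expert, key=expert.get)
    print(f"most expert responses: theme {top} ({expert[top]}); "
          f"patients responded most in theme 5 ({ms.per_theme['5'][0]})")
    print(f"wrote {OUT / 'corpus_per_code.csv'} and {OUT / 'corpus_per_theme.csv'}")


if __name__ == "__main__":
    main()
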
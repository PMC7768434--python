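"""End-to-end pipeline: load -> incidence -> network -> degrees -> bicliques
-> (if labels present) concern multigraph -> report files.

Three input modes, exactly one active per run:

* ``files``     — codebook/roster/responses CSVs supplied by the caller;
* ``fixture``   — the packaged published-marginal corpus, realised as a
                  marginal-consistent synthetic incidence plus the packaged
                  synthetic concern splits (seeded);
* ``synthetic`` — a corpus drawn from :class:`~qualnet.synthetic.GeneratorConfig`.

The pipeline applies no transformation that the individual module operations
do not: its outputs equal composing them by hand.  Every stage logs its
input/output cardinalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import biclique as bq
from . import coding_data as cd
from . import concerns as cn
from . import network as nw
from . import synthetic as syn
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_report"]


@dataclass(frozen=True)
class PipelineConfig:
    mode: Literal["files", "fixture", "synthetic"] = "fixture"
    codebook_path: str | None = None
    roster_path: str | None = None
    responses_path: str | None = None
    synthetic_config: syn.GeneratorConfig | None = None
    min_codes: int = 1
    min_interviewees: int = 1
    export_formats: tuple[str, ...] = ("graphml",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "files":
            if not (self.codebook_path and self.roster_path and self.responses_path):
                raise ValidationError(
                    "files mode needs codebook, roster and responses paths"
                )
        elif self.mode not in ("fixture", "synthetic"):
            raise ValidationError(f"unknown pipeline mode {self.mode!r}")


@dataclass
class ReportBundle:
    codebook: cd.Codebook
    roster: tuple[cd.Interviewee, ...]
    incidence: cd.IncidenceMatrix
    marginals: cd.MarginalSummary
    network: nw.InterviewNetwork
    degrees: nw.NodeDegrees
    summary: nw.NetworkSummary
    code_degree_distribution: nw.DegreeDistribution
    interviewee_degree_distribution: nw.DegreeDistribution
    bicliques: list[bq.Biclique]
    biclique_summary: bq.BicliqueSummary
    concern_incidence: cn.ConcernIncidence | None
    concern_network: cn.ConcernMultigraph | None
    controversy: cn.ControversyReport | None
    concern_notice: str | None
    manifest: list[str] = field(default_factory=list)


def _load_inputs(config: PipelineConfig):
    if config.mode == "files":
        codebook = cd.load_codebook(config.codebook_path)
        roster = tuple(cd.load_roster(config.roster_path))
        responses = cd.load_responses(config.responses_path, codebook, roster)
    elif config.mode == "fixture":
        codebook, roster, responses = syn.table1_synthetic_responses(config.seed)
    else:
        gen_cfg = config.synthetic_config or syn.GeneratorConfig(seed=config.seed)
        dataset = syn.generate(gen_cfg)
        codebook, roster, responses = dataset.codebook, dataset.roster, dataset.responses
    return codebook, roster, responses


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage; deterministic given identical inputs and seed."""
    codebook, roster, responses = _load_inputs(config)
    logger.info(
        "load: %d themes, %d codes, %d interviewees, %d responses",
        len(codebook.themes), len(codebook.codes), len(roster), len(responses),
    )
    incidence = cd.build_incidence(responses, codebook, roster)
    logger.info("incidence: %dx%d with %d links", incidence.M, incidence.N,
                incidence.num_links)
    marginals = cd.marginal_summary(incidence, roster, codebook)
    network = nw.build_network(incidence, codebook, roster)
    degs = nw.degrees(network)
    summary = nw.summarize(network, degs)
    logger.info("network: %d nodes, %d links", len(network.node_order), summary.num_links)
    code_dist = nw.degree_distribution(degs, network, "code")
    iv_dist = nw.degree_distribution(degs, network, "interviewee")
    bicliques = bq.enumerate_maximal_bicliques(
        incidence, min_codes=config.min_codes, min_interviewees=config.min_interviewees
    )
    bq_summary = bq.summarize_bicliques(bicliques)
    logger.info("bicliques: %d maximal (min sizes %d, %d)",
                len(bicliques), config.min_codes, config.min_interviewees)

    classification = cn.classify_responses(responses)
    concern_incidence = concern_network = controversy = None
    notice = None
    if classification.labels:
        concern_incidence = cn.build_concern_incidence(classification, codebook)
        concern_network = cn.build_concern_network(concern_incidence)
        controversy = cn.controversy_report(concern_incidence)
        logger.info(
            "concerns: %d codes dichotomized, %d responses excluded, %d codes excluded",
            concern_incidence.M, classification.excluded_responses,
            len(classification.excluded_codes),
        )
    else:
        notice = (
            "no responses carry yes/no concern labels; concern multigraph omitted"
        )
        logger.info("concerns: skipped (%s)", notice)

    return ReportBundle(
        codebook=codebook,
        roster=tuple(roster),
        incidence=incidence,
        marginals=marginals,
        network=network,
        degrees=degs,
        summary=summary,
        code_degree_distribution=code_dist,
        interviewee_degree_distribution=iv_dist,
        bicliques=bicliques,
        biclique_summary=bq_summary,
        concern_incidence=concern_incidence,
        concern_network=concern_network,
        controversy=controversy,
        concern_notice=notice,
    )


# ---------------------------------------------------------------------------
# rendering


def _write_marginal_table(bundle: ReportBundle, path: Path) -> None:
    theme_of = {cid: tid for cid, tid, _ in bundle.codebook.codes}
    labels = {cid: lab for cid, _, lab in bundle.codebook.codes}
    rows = [
        {
            "code_id": cid,
            "theme_id": theme_of[cid],
            "label": labels[cid],
            "patient_responses": p,
            "expert_responses": e,
            "total": p + e,
        }
        for cid, (p, e) in bundle.marginals.per_code.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_biclique_tables(bundle: ReportBundle, out: Path) -> list[Path]:
    rows = [
        {
            "num_codes": bc.size[0],
            "num_interviewees": bc.size[1],
            "codes": ";".join(sorted(bc.code_set)),
            "interviewees": ";".join(sorted(bc.interviewee_set)),
        }
        for bc in bundle.bicliques
    ]
    p1 = out / "bicliques.csv"
    pd.DataFrame(rows, columns=["num_codes", "num_interviewees", "codes",
                                "interviewees"]).to_csv(p1, index=False)
    p2 = out / "biclique_summary.csv"
    pd.DataFrame(
        [
            {"num_codes": k[0], "num_interviewees": k[1], "frequency": v}
            for k, v in bundle.biclique_summary.frequency.items()
        ],
        columns=["num_codes", "num_interviewees", "frequency"],
    ).to_csv(p2, index=False)
    return [p1, p2]


def _plot_degree_distributions(bundle: ReportBundle, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, dist, title in (
        (axes[0], bundle.interviewee_degree_distribution,
         "codes addressed per interviewee"),
        (axes[1], bundle.code_degree_distribution,
         "interviewees per code"),
    ):
        ax.bar(list(dist.histogram.keys()), list(dist.histogram.values()),
               color="steelblue")
        ax.set_xlabel("degree")
        ax.set_ylabel("number of nodes")
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_biclique_sizes(bundle: ReportBundle, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    freq = bundle.biclique_summary.frequency
    if freq:
        xs = [k[1] for k in freq]  # interviewees
        ys = [k[0] for k in freq]  # codes
        ax.scatter(xs, ys, s=[20 + 8 * v for v in freq.values()], alpha=0.7)
        for (nc, ni), v in freq.items():
            ax.annotate(str(v), (ni, nc), fontsize=7,
                        textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("number of interviewees")
    ax.set_ylabel("number of codes")
    ax.set_title("maximal biclique sizes (annotated: frequency)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _summary_text(bundle: ReportBundle) -> str:
    s = bundle.summary
    lines = [
        f"themes: {len(bundle.codebook.themes)}",
        f"codes: {len(bundle.codebook.codes)}",
        f"interviewees: {len(bundle.roster)}",
        f"links: {s.num_links}",
        f"max code degree: {s.max_code_degree[0]} "
        f"({', '.join(s.max_code_degree[1])})",
        f"max interviewee degree: {s.max_interviewee_degree[0]} "
        f"({', '.join(s.max_interviewee_degree[1])})",
        f"mean code degree (rounded): {s.mean_code_degree_rounded}",
        f"mean interviewee degree (rounded): {s.mean_interviewee_degree_rounded}",
        f"maximal bicliques: {bundle.biclique_summary.total}",
    ]
    if bundle.controversy is not None and bundle.concern_incidence is not None:
        c = bundle.controversy
        lines += [
            f"dichotomized codes: {bundle.concern_incidence.M}",
            f"no-concern codes: {len(c.no_concern)}",
            f"controversial codes: {len(c.controversial)}",
            f"all-concern codes: {len(c.all_concern)}",
        ]
    elif bundle.concern_notice:
        lines.append(f"concerns: {bundle.concern_notice}")
    return "\n".join(lines) + "\n"


def render_report(
    bundle: ReportBundle,
    out_dir,
    export_formats: Sequence[str] = ("graphml",),
) -> list[str]:
    """Write CSV tables, graph exports, plots and a plain-text summary.

    Returns the manifest of written paths (also stored on the bundle).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out / "marginal_summary.csv"
    _write_marginal_table(bundle, p)
    written.append(p)

    p = out / "theme_totals.csv"
    pd.DataFrame(
        [
            {"theme_id": tid, "patient_responses": pe[0], "expert_responses": pe[1],
             "total": pe[0] + pe[1]}
            for tid, pe in bundle.marginals.per_theme.items()
        ]
    ).to_csv(p, index=False)
    written.append(p)

    for dist, name in (
        (bundle.code_degree_distribution, "degree_distribution_codes.csv"),
        (bundle.interviewee_degree_distribution, "degree_distribution_interviewees.csv"),
    ):
        p = out / name
        pd.DataFrame(
            [{"degree": d, "count": c} for d, c in dist.histogram.items()],
            columns=["degree", "count"],
        ).to_csv(p, index=False)
        written.append(p)

    written += _write_biclique_tables(bundle, out)

    for fmt in export_formats:
        p = out / f"interview_network.{fmt}"
        nw.export_graph(bundle.network, fmt, p)
        written.append(p)

    if bundle.concern_incidence is not None:
        p = out / "concern_incidence.csv"
        pd.DataFrame(
            {
                "code_id": list(bundle.concern_incidence.code_index),
                "yes_count": bundle.concern_incidence.Bp[:, 0],
                "no_count": bundle.concern_incidence.Bp[:, 1],
            }
        ).to_csv(p, index=False)
        written.append(p)
        assert bundle.controversy is not None
        p = out / "controversy.csv"
        cat = {}
        for cid in bundle.controversy.no_concern:
            cat[cid] = "no_concern"
        for cid in bundle.controversy.all_concern:
            cat[cid] = "all_concern"
        for cid in bundle.controversy.controversial:
            cat[cid] = "controversial"
        pd.DataFrame(
            [{"code_id": cid, "category": cat[cid]}
             for cid in bundle.concern_incidence.code_index]
        ).to_csv(p, index=False)
        written.append(p)
        for fmt in export_formats:
            p = out / f"concern_network.{fmt}"
            cn.export_concern_graph(bundle.concern_network, fmt, p)
            written.append(p)

    p = out / "degree_distributions.png"
    _plot_degree_distributions(bundle, p)
    written.append(p)
    p = out / "biclique_sizes.png"
    _plot_biclique_sizes(bundle, p)
    written.append(p)

    p = out / "summary.txt"
    p.write_text(_summary_text(bundle))
    written.append(p)

    bundle.manifest = [str(w) for w in written]
    return bundle.manifest
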
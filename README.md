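# qualnet

Two-mode network analysis of thematically coded qualitative interview data.

Mixed-methods interview studies produce a corpus of *codes* — labelled
categories into which an analyst sorts matching interview phrases — grouped
into higher-level *themes*, together with a record of which interviewee
addressed which code. `qualnet` turns such a coded corpus into quantitative,
reproducible network analyses for health-services and social-science
researchers: who talked about what, which topics cluster on the same people,
and where stakeholders disagree about whether a topic is a concern.

## The model

Let *C* = {1, …, *M*} index the codes and *I* = {1, …, *N*} the interviewees.
The corpus defines a binary **incidence matrix** *B* with

  *b<sub>ij</sub>* = 1 if interviewee *j* responded to code *i*, else 0,

and the **bipartite interview network** 𝒩 with block adjacency

  *A* = [[0<sub>M×M</sub>, B], [*B*ᵀ, 0<sub>N×N</sub>]].

A node's degree *k<sub>l</sub>* (row sum of *A*) counts the interviewees
addressing a code, or the codes addressed by an interviewee. **Maximal
bicliques** ("concepts") — pairs of a code set and an interviewee set, every
cross pair linked, extendable by no further node — expose the structurally
strongest response patterns; `qualnet` enumerates them exhaustively via
closure (NextClosure) over the smaller partition. Finally, each response can
be dichotomized by its key statement into "yes" (concern voiced — the
negatively connoted option) or "no"; the per-code counts #y<sub>i</sub> and
#n<sub>i</sub> form the M′×2 matrix *B*′ of a weighted **concern multigraph**
𝒩<sub>𝒞</sub> linking codes to a yes node and a no node, and codes partition
into *no-concern* (#y = 0), *all-concern* (#n = 0) and *controversial* (both
positive).

The package includes a fixture carrying the published per-code
patient/expert response marginals of a 16-interviewee (2 cancer patients,
10 clinicians/health-system experts, 4 basic scientists), 43-code corpus on
personalized oncological medicine in Austria. The interviewee-level matrix
behind that corpus is not public; demonstration networks are drawn
marginal-consistently at random and are documented as synthetic throughout.
A seeded generator (`qualnet.synthetic`) produces fully synthetic corpora
with role- and theme-dependent response probabilities, plantable bicliques
and concern labels, so every pipeline stage is testable without any
download.

## Worked example

```python
import qualnet as qn

codebook, marginals = qn.table1_fixture()
roster = qn.table1_roster()
inc = qn.table1_consistent_incidence(seed=1)   # marginal-consistent draw
net = qn.build_network(inc, codebook, roster)
summary = qn.summarize(net, qn.degrees(net))
print(summary.num_links, summary.max_code_degree, summary.mean_interviewee_degree_rounded)
# 220 (11, ('7.8',)) 14

bicliques = qn.enumerate_maximal_bicliques(inc)
print(len(bicliques), bicliques[0].size)
# 312 (18, 1)

cb, _, responses = qn.table1_synthetic_responses(seed=1)
ci = qn.build_concern_incidence(qn.classify_responses(responses), cb)
rep = qn.controversy_report(ci)
print(ci.M, len(rep.no_concern), len(rep.controversial), len(rep.all_concern))
# 28 5 11 12
```

The corpus has 220 links; its most-addressed code is 7.8 (best
decision-making, 11 of 16 interviewees — experts only), the average
interviewee addressed 14 codes and the average code was addressed by 5
interviewees. Of the 28 dichotomizable codes, 5 drew no concerns, 11 were
controversial and 12 drew concerns from every respondent. (The biclique
census — here 312 maximal bicliques — depends on the synthetic realisation
of the unpublished interviewee-level matrix.)

The same pipeline runs from the command line:

```sh
qualnet report --fixture-table1 --seed 1 --out out/
qualnet simulate --seed 2 --out sim/          # fully synthetic corpus
qualnet bicliques --codebook cb.csv --roster roster.csv --responses resp.csv \
        --min-codes 2 --min-interviewees 2 --out out/
```

The numbered scripts under `analysis/` walk the full study — corpus
marginals, network degrees, biclique census, concern multigraph, generator
calibration — writing tables and plots to `results/`.

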
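# ssetopo

Ranking protein secondary-structure topologies by combining 1D, 2D and 3D
evidence.

## The problem

At medium resolution (5–10 Å), a cryo-EM density map resolves the shapes of
α-helices and β-sheets but not individual atoms. Detection tools can turn
such a map into a set of *traces* — straight 3D line segments standing for
helix axes and strand paths — while sequence-based predictors provide the
*segments*: the stretches of the chain expected to form helices and strands.
Neither source says which segment corresponds to which trace. That
correspondence, an ordered and directed assignment of segments to traces
from the N- to the C-terminus, is the **secondary-structure topology** of
the chain, and it is the scaffold from which a tertiary model can be built.

With `M` segments and `N` traces of one type, the candidate space holds

    C(max(M,N), min(M,N)) · min(M,N)! · 2^min(M,N)

topologies (subset choice × order × two directions per matched trace); mixed
α/β proteins multiply the per-type spaces. `ssetopo` ranks this space using
three independent information sources:

1. **1D** — segments parsed from a 3-state secondary-structure prediction
   (predicted helices shorter than 3 residues are ignored);
2. **2D** — predicted residue–residue contacts (CASP RR format), screened
   down to the significant long-range pairs and aggregated to pairs of
   segments in contact;
3. **3D** — the traces themselves, plus optionally the density-map skeleton,
   along which inter-trace distances are measured.

The initial ranking scores each topology by loop-length agreement: a loop of
`r` residues can span at most `3.8·r` Å, so each consecutive matched pair
contributes `max(0, observed_gap − 3.8·r − slack)`, where the observed gap
runs from the C-side exit of the earlier trace to the N-side entry of the
later one (along the skeleton when available). The top-k list is found
exactly by best-first search over the layered assignment graph; both `M ≥ N`
and `M < N` are supported.

Re-ranking then checks each candidate against the screened contacts. For a
topology, `CP` counts the contact-supported segment pairs whose segments are
both assigned traces, and `SP` counts those whose traces lie within 13 Å
(shortest line-to-line distance). Candidates are ordered by `SP/CP`, giving
each a `Rank_update`, and the final order fuses the two ranks:

    score = a · Rank_init + (1 − a) · Rank_update,      a = 0.7

Rankings are evaluated against a ground-truth correspondence by the
**maximum-match** criterion: the number of (segment, trace, direction)
matches agreeing with the truth, and the best rank at which that maximum is
achieved.

## Worked example

The package ships a synthetic-case generator that emulates the upstream
tools (secondary-structure prediction, contact prediction, trace detection,
skeletonization) on an idealized helix-bundle + sheet fold:

```python
from ssetopo import (
    SyntheticSpec, make_case, rank_topologies_dp, DPConfig,
    filter_long_range, select_significant, ScreeningConfig,
    rerank, max_match_rank,
)

case = make_case(SyntheticSpec(n_helices=5, n_strands=3, seed=3))
print(f"{len(case.segments)} segments, {len(case.traces)} traces, "
      f"{len(case.sequence)} residues")

ranked = rank_topologies_dp(case.segments, case.traces, case.skeleton,
                            DPConfig(k_top=50))
print("best score:", round(ranked[0].dp_score, 2),
      "| runner-up:", round(ranked[1].dp_score, 2))

cfg = ScreeningConfig()
screen = select_significant(filter_long_range(case.contacts, cfg),
                            case.segments, cfg)
print(f"screen stopped at {screen.sd_level}SD with "
      f"{len(screen.selected)} contacts on {len(screen.ss_pairs)} segment pairs")

final = rerank(ranked, list(screen.ss_pairs), case.traces)
rank, pairs = max_match_rank(final, case.truth)
print(f"maximum-match topology: {pairs} correct pairs at final rank {rank} "
      f"(CP={final[0].cp}, SP={final[0].sp})")
```

Output:

```
8 segments, 8 traces, 92 residues
best score: 0.0 | runner-up: 7.01
screen stopped at 3.0SD with 60 contacts on 7 segment pairs
maximum-match topology: 8 correct pairs at final rank 1 (CP=7, SP=7)
```

The true topology scores 0 (every loop fits its gap), the best wrong
candidate pays a 7 Å mismatch, and the screen recovers the seven adjacent
segment pairs of the fold; all seven are satisfied by the top candidate's
trace geometry, so re-ranking keeps it first.

The same pipeline is available from the shell:

```bash
ssetopo simulate --seed 3 --out-dir case/
ssetopo rank --sequence case/sequence.fasta --segments case/ss_prediction.txt \
             --traces case/traces.tsv --skeleton case/skeleton.xyz --out topo.tsv
ssetopo screen-contacts --contacts case/contacts.rr --sequence case/sequence.fasta \
             --segments case/ss_prediction.txt --out ss_contacts.tsv
ssetopo rerank --topologies topo.tsv --ss-contacts ss_contacts.tsv \
             --traces case/traces.tsv --out final.tsv
ssetopo evaluate --topologies final.tsv --truth case/truth.tsv
```

or end-to-end with `ssetopo run-all --config config.txt --out-dir out/`.

## File formats

All formats are plain text (see `ssetopo/io.py` docstrings): FASTA
sequences, 3-state secondary-structure strings, CASP RR contacts, traces as
`id type x1 y1 z1 x2 y2 z2`, skeletons as XYZ points, tab-separated
topology tables and ground-truth correspondences. Residue indices are
1-based inclusive; coordinates are in Ångström.
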
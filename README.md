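# taledesign

Design genome-orthogonal TALE effector-binding elements (EBEs) and audit
their off-target landscape.

Designer TALEs (dTALEs) are programmable transcription activators: a
tandem repeat array reads DNA one base per repeat (RVDs HD→C, NN→G, NI→A,
NG→T, after an invariant 5′ thymine T0), so a dTALE plus a synthetic
promoter carrying its 19-bp binding element forms a portable expression
module. The module is only orthogonal if the EBE — and everything near it
in sequence space — is effectively absent from the host genome. This
package is for synthetic biologists building such systems in plants (or
any sequenced host): it generates candidate EBEs, finds every genomic
near-match, scores how dangerous each near-match is, picks the most
orthogonal candidate, and reports where a chosen EBE's off-target sites
fall relative to genes.

## The scoring model

A genomic window differing from a candidate EBE at positions
p₁, …, p_m gets the off-target score

    S_OFF = Σᵢ F_P(pᵢ) · S_M(RVDᵢ, baseᵢ)
    F_P(p) = 1/√p            (T0-proximal mismatches weigh most)
    S_M    = (preference − 0.5) · (−2)   ∈ [−1, 1]

where the preference in [0, 1] rates how well the designed repeat
tolerates the genomic base. High S_OFF = disruptive mismatches = safe
site. For each candidate, the 200 closest off-targets with ≥3 mismatches
are scored; their mean is the **neverword score S_N**, and the ratio of
the mean of the 100 lowest scores to the mean of the remaining 100 flags
uneven risk (ratio ≈ 1 is good). The selected design is the candidate
with the highest S_N, ties broken by the ratio closest to 1. The genome
search itself is an exact pigeonhole-seeded mismatch scan (≤ k mismatches
⇒ one of k+1 query blocks matches exactly), verified against a
brute-force oracle.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations — in particular, the built-in RVD-base preference matrix is a
structural default derived from the canonical code; quantitative
preference tables can be supplied as a TSV.

## Worked example

Build a synthetic 20 kb genome with two planted near-matches of a known
EBE, design a new orthogonal EBE against it, then audit the known EBE:

```
$ taledesign --seed 7 --out demo fixtures --genome-length 20000 --n-genes 4 \
      --plant TCCCCGCATAGCTGAACAT:3:+ --plant TCCCCGCATAGCTGAACAT:4:-
wrote fixture genome (20000 bp, 2 plants) to demo

$ taledesign --seed 7 --out demo design demo/genome.fasta -n 30
selected TTACCAGGGTGCCTTTTAC S_N=2.4214 ratio=0.7268

$ printf '>dtale1\nTCCCCGCATAGCTGAACAT\n' > demo/ebe.fa
$ taledesign --seed 7 --out demo audit demo/ebe.fa demo/genome.fasta \
      --annotation demo/annotation.gff3
census (0bp: 0, 1bp: 0, 2bp: 0, 3bp: 1, 4bp: 1); outputs in demo
```

The design run generated 30 T-initial candidates, kept the ones at
Hamming distance ≥3 from every genomic window on either strand, scored
each candidate's closest off-targets and ranked them
(`demo/ranked_candidates.tsv`):

```
# rank  sequence             s_n       ratio    n_scored  short_set  ...
1       TTACCAGGGTGCCTTTTAC  2.42135   0.72676  4         1
2       TCCAGGGCTGCTTGAGGAG  2.41395   NA       1         1
```

Rank 1 is the selected design: of all candidates it has the highest mean
off-target score (its nearest genomic neighbours are the most disrupted),
with the score distribution closest to even. On a 20 kb toy genome each
candidate has only a handful of scorable neighbours (`n_scored` ≪ 200, so
`short_set` is flagged); on a real genome the standard 200 closest sites
are scored. The audit census confirms the two planted sites — one at 3
and one at 4 mismatches, nothing closer — and `demo/categories.tsv`
tabulates the genes each off-target site lands in or near (CDS, UTRs,
intron, upstream, downstream, intergenic within 5 kbp).

The same operations are available as a library
(`taledesign.run_design`, `taledesign.run_audit`, `taledesign.scan_genome`,
…), which is what the test suite and the acceptance script drive.

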
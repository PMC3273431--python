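# kunitzkit

Analysis toolkit for the **Kunitz/BPTI gene family in ticks**: the
disulfide-stabilized ~60-aa Kunitz domain is the workhorse of tick saliva —
inhibiting host serine proteases (the ancestral function, via the P1
residue; Lys15 in BPTI) or modulating ion channels (a derived function of
lineage-specific groups in *Ixodes*).  `kunitzkit` is for researchers who
want to reproduce or extend this style of gene-family analysis: detect and
classify domains, annotate functional sites, quantify stage-specific
expression from EST libraries, build trees, and test for positive
selection — all from plain FASTA/TSV/newick inputs, with generators for
fully synthetic test data.

## What it computes

* **Domain scan** — six-cysteine windows matched against the group spacing
  patterns C-X(8)-C-X(15)-C-X(7)-C-X(12)-C-X(3)-C (group I),
  C-X(8)-C-X(18)-C-X(5)-C-X(12)-C-X(3)-C (II) and
  C-X(5,6)-C-X(15)-C-X(8)-C-X(11)-C-X(3)-C (III); architecture labels
  One-KU … Seven-KU; multi-domain splitting.
* **Functional sites** — P1 = the residue after C2; trypsin motif
  C₂-[K/R]-small, chymotrypsin motif C₂-[F/L/N/Y]-small; channel-modulating
  elements (R/K near L/Y/F in the domain "base").
* **Expression** — the EST heterogeneity statistic
  R = Σⱼ xⱼ ln(xⱼ / (Nⱼ f)), f = Σxⱼ/ΣNⱼ, with simulation-based
  believability and calls at R ≥ 9, believability ≥ 99%; stage patterns
  (late-only vs mid-feeding burst).
* **Phylogenetics** — p/Poisson protein distances, deterministic
  neighbor joining, Felsenstein column bootstrap.
* **Selection** — GY94 codon site models M0/M1a/M2a/M3/M7/M8 (ω = dN/dS
  class mixtures), likelihood ratio tests (2ΔL vs χ², critical values 9.21
  at df=2 and 13.28 at df=4 at the 1% level), NEB/BEB site posteriors
  (positive sites at posterior > 0.95), PAL2NAL-style codon threading and a
  Nei–Gojobori counting cross-check.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import numpy as np
from kunitzkit import (SequenceRecord, scan_record, locate_p1,
                       classify_inhibitor, r_statistic)

# mature BPTI (UniProt P00974)
bpti = SequenceRecord(
    id="BPTI",
    residues="RPDFCLEPPYTGPCKARIIRYFYNAKAGLCQTFVYGGCRAKRNNFKSAEDCMRTCGGA",
)
(dom,) = scan_record(bpti)
print(dom.spacing, dom.group, dom.exact_match)
pos, aa = locate_p1(dom, bpti)
print(pos + 1, aa, classify_inhibitor(dom, bpti))

# the mid-feeding burst gene (counts 0/17/259/2 across four staged
# libraries of 10,000 ESTs each)
print(round(r_statistic([0, 17, 259, 2], [10000] * 4), 2))
```

prints

```
(8, 15, 7, 12, 3) I True
15 K trypsin
309.68
```

— one canonical group-I domain, the P1 site at mature position 15 (a
lysine, hence a trypsin-inhibitor motif), and an R statistic far above the
significance cutoff of 9 for the burst-shaped expression profile.

The same stages are available from the shell:

```bash
kunitzkit simulate proteins --n 10 --group II --seed 1 --out proteins.faa
kunitzkit scan --fasta proteins.faa --out domains.json
kunitzkit annotate --fasta proteins.faa --out annotations.json
kunitzkit express --counts counts.tsv --seed 1 --out expression.json
kunitzkit tree --fasta aln.faa --bootstrap 100 --seed 1 --out tree.nwk
kunitzkit selection --alignment aln.faa --cds cds.fna --tree tree.nwk \
    --models M0,M1a,M2a --seed 1 --out selection.json
kunitzkit run --config pipeline.json   # all stages from one JSON config
```

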
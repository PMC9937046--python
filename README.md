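# imprintase

Reciprocal-cross allele-specific-expression analysis for discovering
imprinted genes, built for F1 hybrid RNA-seq designs such as crosses between
the laboratory opossum (*Monodelphis domestica*) stocks LL1 and LL2.

Genomic imprinting is parent-of-origin-dependent monoallelic expression.
In a reciprocal cross — LL1 dam × LL2 sire, and the mirror-image mating —
the parental origin of every allele can be tracked in the F1s at
*informative SNPs*: sites where the two stocks are fixed for opposite
alleles. Writing p₁ for the LL1-allele expression fraction in the LL1×LL2
cross and p₂ for the same fraction in the LL2×LL1 cross, an imprinted gene
shows a **flipped** allelic bias:

- **MEG** (maternally expressed): p₁ > 0.65 and p₂ < 0.35
- **PEG** (paternally expressed): p₁ < 0.35 and p₂ > 0.65

whereas a *cis*-eQTL keeps its bias on the same side of 0.5 in both
directions and is never called imprinted. Genes on unplaced/X scaffolds
with ~100% maternal expression in every library are flagged as imprinted-X
inactivation (XCI) candidates rather than autosomal MEGs. With coverage
fraction *c* (expressed genes reachable by informative SNPs) and *n*
detected autosomal MEG+PEG genes, the genome-wide imprinted count is
extrapolated as *n*/*c* with a Clopper–Pearson interval scaled the same
way.

The package covers every stage without external data:

- `imprintase.simulate` — seeded reciprocal-cross generator with known
  truth (biallelic / MEG / PEG / cis-eQTL / XCI gene classes, two-stock
  site polymorphism model, negative-binomial depth), plus bisulfite clone
  simulation;
- `imprintase.snps` — count/VCF ingestion, 40× pooled-depth SNP discovery,
  stock genotyping with a confirmed-genotype override, informativeness
  (opposite homozygotes, ≥8× per stock and ≥3 of 4 F1 libraries), repeat
  and exon-junction masking;
- `imprintase.ase` — per-SNP allelic ratios and count-pooled gene×tissue
  p₁/p₂ summaries with an FPKM ≥ 1 detection gate;
- `imprintase.caller` — flipped-pattern MEG/PEG classifier, XCI flagging,
  cross-tissue summaries;
- `imprintase.methylation` — bisulfite clone calling from sequences or
  M/U matrices, per-CpG percentages, allele partitioning, and promoter
  DMR classification (≈50% aggregate methylation with divergent allele
  means is the DMR hallmark);
- `imprintase.estimate` — coverage fraction and genome-wide extrapolation.

## Worked example

The packaged fixture carries the published allelic percentages of ten novel
imprinted genes. Calling them:

```python
from imprintase import datasets, caller, estimate

calls = caller.call_genes(datasets.table1_gene_ase())
print(calls[calls.tissue == "fetal_brain"][
    ["gene_id", "status", "expressed_parent", "p1", "p2"]].to_string(index=False))
```

```
 gene_id status expressed_parent    p1    p2
  Ipncr1    MEG         maternal 0.955 0.045
  Pou5f3    PEG         paternal 0.022 0.978
   Npdc1    PEG         paternal 0.023 0.977
  Rwdd2a    PEG         paternal 0.006 0.994
   Zfp68    PEG         paternal 0.000 1.000
  Ipncr5    PEG         paternal 0.019 0.981
  Ipncr2    PEG         paternal 0.014 0.986
  Nkrfl1    PEG         paternal 0.001 0.999
  Nkrfl2    PEG         paternal 0.001 0.999
 Fam169a    MEG         maternal 0.986 0.014
```

Ten genes are imprinted in fetal brain (8 PEG, 2 MEG). Summarising across
tissues shows eight imprinted in both fetal brain and placenta, with
*Ipncr1* and *Ipncr2* undetectable in placenta:

```python
summary = caller.summarize_calls(calls)
summary["imprinted_both"]
# ['Fam169a', 'Ipncr5', 'Nkrfl1', 'Nkrfl2', 'Npdc1', 'Pou5f3', 'Rwdd2a', 'Zfp68']
```

Extrapolating 12 detected autosomal imprinted genes at 20% informative
coverage:

```python
estimate.extrapolate_total(12, 0.20, n_covered=3025)
# GenomeEstimate(n_detected=12, coverage_fraction=0.2, extrapolated_total=60.0,
#                interval=(31.03, 104.65))
```

— about 60 imprinted genes genome-wide.

A full simulated run from the shell:

```bash
imprintase run-all config.yaml --outdir out/
```

with a `config.yaml` like

```yaml
seed: 1
simulate: {n_genes: 300}
thresholds: {min_pooled_depth: 40, upper: 0.65, lower: 0.35}
```

writes counts, informative-SNP ratios, calls, a JSON summary and an
auditable `run_log.jsonl`.

## Acceptance script

`scripts/acceptance.py` re-runs the end-to-end pipeline on a seeded
simulated dataset (simulate → filter → ASE → call → XCI flag → genome-wide
estimate) and writes its JSON result file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the model, the synthetic-data generator's
assumptions, numerical choices and known limitations.
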
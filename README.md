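# recmap

Mapping recessive defects in pedigreed livestock populations.

Some bulls with entirely normal semen quality sire almost no calves.  When
such idiopathic subfertility is a recessive Mendelian defect descending
from a single popular ancestor, it leaves a characteristic statistical
footprint: a strong association signal for the fertility score on one
chromosome, a chromosome segment that all affected sires carry in the
homozygous state and no normal sire does, and — in whole-genome sequence
of known haplotype carriers — a rare variant heterozygous in every carrier.
`recmap` implements that whole mapping chain as reusable, tested
components, together with a gene-drop simulator that reproduces the
population structure the chain assumes, so every stage can be exercised
end-to-end without proprietary breeding data.

## The models

**Mixed-model genome scan.**  For phenotypes *y* (a fertility score
expressed as percentage deviation from the population mean, or a 0/1
case indicator) each marker is tested in

> *y* = *Xb* + *u* + *e*,  *u* ~ N(0, σ²ₐ **G**),  *e* ~ N(0, σ²ₑ **I**)

with **G** the realized genomic relationship matrix
**WW**′ / 2Σpₖ(1−pₖ) from centred dosages.  (σ²ₐ, σ²ₑ) are estimated once
under the null by REML — one spectral decomposition of **G**, a
one-dimensional search over δ = σ²ₑ/σ²ₐ — and held fixed for every
per-marker Wald test (the EMMAX approximation), so a scan costs O(n) per
marker after rotation.

**Autozygosity mapping.**  Each affected individual's run of homozygosity
around an anchor marker is extended maximally (0 heterozygous calls
allowed by default, missing calls ignored); the shared segment is the
marker-index intersection over cases.  Copies of the case consensus
haplotype are then counted per individual in phased data, giving
diplotype counts for Hardy-Weinberg tests (χ², 1 df), carrier-frequency
trends over birth years, mixed-model dosage effects on other traits, and
insemination-success summaries.

**Recessive-compatibility filter.**  Sequence-panel variants compatible
with the mapped haplotype are kept either strictly (heterozygous in all
carriers, homozygous reference in all non-carriers) or conservatively for
low-coverage data: non-reference allele frequency below 10%, heterozygous
in the one high-coverage carrier, and heterozygous in at least 3 of the 5
low-coverage carriers — tolerating the heterozygote under-calls
low-coverage sequencing produces.

**Consequence annotation.**  Surviving substitutions are mapped through a
single-transcript gene model (both strands) to a spliced-CDS position,
the affected codon ⌈cds/3⌉ is translated ref and alt with the standard
genetic code, and stop-gains are named HGVS-style (`p.Cys161X`) with
their truncation length.

## Worked example

Run the full pipeline on a simulated population — 2100 animals over six
generations, a deleterious haplotype implanted on one founder chromosome
at ~7% target frequency, homozygotes shifted to the subfertile trait
distribution, and a 43-sample resequencing panel with one high- and five
low-coverage carriers:

```python
from recmap.pipeline import run_pipeline

report = run_pipeline(
    {
        "seed": 3,
        "simulate": {"n_founders": 350, "n_generations": 6,
                     "n_markers": 250, "chrom_length_bp": 2_000_000},
        "panel": {"n_region_variants": 120},
    },
    out_dir="out",
)
```

This prints (via `out/report.md`, abridged):

```
top marker      M00125 at 19:947299  (P = 7.51e-14, n = 2100)
shared segment  19:802999-1100189  (297 kb, 38 markers, 2 cases)
diplotypes      1895/203/2  (haplotype frequency 4.9%, HWE P = 0.149)
controls homozygous: 0
scan            1 of 120 region variants retained (105 SNPs + 15 INDELs in region)
candidate       TMEM95 c.483C>A (p.Cys161X), stop-gain truncating 22 residues at 19:948385
```

Reading it: the case/control scan puts its strongest signal next to the
implanted locus; the two subfertile homozygotes share a 297 kb homozygous
segment that no control carries homozygously; diplotype counts in the
population fit Hardy-Weinberg (so nothing but male subfertility selects
against the haplotype); exactly one region variant is compatible with
recessive inheritance, and it is the implanted stop-gain — a premature
stop at codon 161 of the 183-residue transmembrane protein, removing the
last 22 residues.  Re-running with the same seed reproduces `report.json`
byte for byte.

The same stages are available as a CLI (`recmap simulate|qc|gwas|roh|
hapstats|scan|annotate|run|validate`) and as library calls; the scan
itself follows the model/results idiom:

```python
from recmap import MixedModelGWAS
results = MixedModelGWAS.from_tables(phenotypes, genotypes, trait="mra").fit()
print(results.summary())        # variance components, h2, top markers
results.table                   # per-marker effect, SE, statistic, p
```

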
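"""Readers and writers for the plain-text interchange formats.

Genotypes travel as VCF 4.2 (phased ``|`` genotypes when phase is known)
or as a simple tab-separated dialect with one row per individual and one
0/1/2/NA column per marker.  Phenotypes, pedigrees, gene models and QC
reports are tab-separated tables with a header; references are FASTA.
VCF parsing is delegated to ``cyvcf2``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .genotypes import MISSING, GenotypeMatrix
from .scan import SequencePanel, variant_type


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def read_pedigree(path):
    from .simulate import Pedigree

    table = read_table(path)
    table = table.where(pd.notna(table), None)
    if "sire" in table:
        table["sire"] = [None if pd.isna(x) else str(x) for x in table["sire"]]
        table["dam"] = [None if pd.isna(x) else str(x) for x in table["dam"]]
    return Pedigree(table)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                sequences[name] = []
            elif name is not None:
                sequences[name].append(line)
    return {k: "".join(v) for k, v in sequences.items()}


# ---------------------------------------------------------------------------
# individual-level genotypes
# ---------------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a biallelic-SNP VCF; phased ``a|b`` genotypes when phase exists.

    Phased output is written from the haplotypes (the complete truth in
    simulated data); unphased output encodes calls with ``./.`` for missing.
    """
    markers = geno.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(markers["chrom"]):
            length = int(markers.loc[markers["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in geno.ids)
            + "\n"
        )
        phased = geno.phased
        for j in range(geno.n_markers):
            rec = markers.iloc[j]
            if phased:
                h = geno.haplotypes[:, :, j]
                gts = [
                    "|".join("." if a == MISSING else str(int(a)) for a in pair)
                    for pair in h
                ]
            else:
                coded = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [coded[int(c)] for c in geno.calls[:, j]]
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['name']}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Haplotypes are retained when every genotype in the file is phased;
    otherwise the matrix is unphased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    names, chroms, poss, refs, alts = [], [], [], [], []
    hap_rows = []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            raise InputError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; decompose first"
            )
        names.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        row = np.empty((len(ids), 2), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            row[i, 0] = MISSING if a < 0 else a
            row[i, 1] = MISSING if b < 0 else b
            if not g[2]:
                all_phased = False
        hap_rows.append(row)
    vcf.close()
    markers = pd.DataFrame(
        {"name": names, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    haps = np.transpose(np.array(hap_rows, dtype=np.int8), (1, 2, 0))  # (n, 2, m)
    calls = np.where((haps == MISSING).any(axis=1), MISSING, haps.sum(axis=1)).astype(
        np.int8
    )
    return GenotypeMatrix(
        ids=ids,
        calls=calls,
        markers=markers,
        haplotypes=haps if all_phased else None,
    )


def write_genotype_tsv(geno: GenotypeMatrix, path) -> None:
    """Array-style genotypes: one row per individual, 0/1/2/NA per marker."""
    table = pd.DataFrame(
        geno.calls.astype(float), columns=geno.markers["name"], index=geno.ids
    )
    table[geno.calls == MISSING] = np.nan
    table = table.astype("Int64")
    table.insert(0, "id", geno.ids)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotype_tsv(path, markers: pd.DataFrame) -> GenotypeMatrix:
    """Read the 0/1/2/NA dialect; ``markers`` supplies the marker map."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    ids = table["id"].astype(str).to_numpy(dtype=object)
    cols = list(markers["name"])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise InputError(f"genotype table lacks markers {missing[:5]}...")
    calls = table[cols].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(ids=ids, calls=calls, markers=markers.reset_index(drop=True))


# ---------------------------------------------------------------------------
# resequencing panel
# ---------------------------------------------------------------------------

_PANEL_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_PANEL_GT_INV = {v: k for k, v in _PANEL_GT.items()}


def write_panel_vcf(panel: SequencePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.variants["chrom"]):
            sub = panel.variants[panel.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.samples)
            + "\n"
        )
        for i in range(panel.n_variants):
            rec = panel.variants.iloc[i]
            gts = "\t".join(_PANEL_GT[int(g)] for g in panel.genotypes[i])
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\tV{i:05d}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_panel_samples(panel: SequencePanel, path) -> None:
    write_table(
        pd.DataFrame(
            {
                "sample": panel.samples,
                "carrier": panel.carrier.astype(int),
                "coverage_class": panel.coverage,
            }
        ),
        path,
    )


def read_panel_samples(path) -> pd.DataFrame:
    table = read_table(path)
    required = {"sample", "carrier", "coverage_class"}
    if not required <= set(table.columns):
        raise InputError(f"panel sample table needs columns {sorted(required)}")
    return table


def read_panel_vcf(path, samples_table: pd.DataFrame) -> SequencePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    ann = samples_table.set_index(samples_table["sample"].astype(str))
    try:
        carrier = np.array([bool(ann.loc[str(s), "carrier"]) for s in samples])
        coverage = np.array(
            [str(ann.loc[str(s), "coverage_class"]) for s in samples], dtype=object
        )
    except KeyError as exc:
        raise InputError(f"sample {exc.args[0]!r} missing from annotation table") from None
    chroms, poss, refs, alts = [], [], [], []
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise InputError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; decompose first"
            )
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            row[i] = MISSING if a < 0 or b < 0 else a + b
        rows.append(row)
    vcf.close()
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    variants["vtype"] = [variant_type(r, a) for r, a in zip(refs, alts)]
    return SequencePanel(
        variants=variants,
        genotypes=np.array(rows, dtype=np.int8),
        samples=samples,
        carrier=carrier,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def read_fixture_bundle(directory) -> dict:
    """Re-read a bundle written by ``write_fixture_bundle``.

    Returns a dict with the reconstructed genotypes (haplotypes from the
    phased VCF, array calls from the tab-separated table), phenotypes,
    pedigree, panel, gene model, reference and manifest.
    """
    import json

    from .annotate import GeneModel

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    geno = read_vcf(directory / files["genotypes_vcf"])
    array = read_genotype_tsv(directory / files["genotypes_tsv"], geno.markers)
    geno.calls = array.calls
    pheno = read_table(directory / files["phenotypes"])
    pedigree = read_pedigree(directory / files["pedigree"])
    panel = read_panel_vcf(
        directory / files["panel_vcf"],
        read_panel_samples(directory / files["panel_samples"]),
    )
    gene_model = GeneModel.from_exon_table(read_table(directory / files["gene_model"]))
    reference = read_fasta(directory / files["reference"])
    return {
        "manifest": manifest,
        "genotypes": geno,
        "phenotypes": pheno,
        "pedigree": pedigree,
        "panel": panel,
        "gene_model": gene_model,
        "reference": reference,
    }
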
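"""End-to-end orchestration of the mapping pipeline.

A single YAML (or dict) config drives the linear stage sequence
simulate/ingest -> QC -> GWAS -> autozygosity mapping -> recessive scan ->
annotation -> report.  Each stage writes its artefacts under its own
subdirectory of ``out_dir``; the final report (markdown + JSON) collects
the headline quantities — top associated marker, shared homozygous
segment, diplotype counts with Hardy-Weinberg p-values, filter survivors
and coding consequences — and ``manifest.json`` records the seed, package
version and input digests so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .annotate import FastaReference, InMemoryReference, annotate_variants
from .exceptions import DependencyError, InputError
from .genotypes import MISSING
from .gwas import MixedModelGWAS, build_grm, case_control_scan
from .qc import QCConfig, apply_qc, differential_missingness
from .roh import (
    Segment,
    call_haplotype_copies,
    carrier_trend,
    diplotype_counts,
    fertility_summary,
    hwe_chisq,
    shared_segment,
)
from .scan import (
    FilterConfig,
    classify_retained,
    conservative_filter,
    genotype_class_report,
    restrict_to_region,
    strict_filter,
)
from .simulate import SequencePanelConfig, SimulationConfig, simulate_study

logger = logging.getLogger("recmap")

STAGES = ("simulate", "qc", "gwas", "roh", "scan", "annotate")

_SCHEMA: dict[str, set] = {
    "": {"seed", "out_dir", "stages", "simulate", "panel", "qc", "gwas", "roh", "scan", "inputs", "log_level"},
    "stages": set(STAGES),
    "simulate": {f for f in SimulationConfig.__dataclass_fields__},
    "panel": {f for f in SequencePanelConfig.__dataclass_fields__},
    "qc": {f for f in QCConfig.__dataclass_fields__},
    "gwas": {"trait", "binary", "case_threshold"},
    "roh": {"max_het", "max_missing", "match_threshold", "anchor"},
    "scan": {"af_max", "min_lc_het", "mode", "region"},
    "inputs": {"bundle"},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        try:
            config = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise InputError(f"cannot parse config{line}: {exc}") from None
    return config or {}


def validate_config(path_or_dict) -> list[str]:
    """Schema check without execution; lists unknown keys and missing files."""
    try:
        config = load_config(path_or_dict)
    except InputError as exc:
        return [str(exc)]
    diagnostics: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    for key in config:
        if key not in _SCHEMA[""]:
            diagnostics.append(f"unknown key: {key}")
    for section, allowed in _SCHEMA.items():
        if not section or section not in config:
            continue
        block = config[section]
        if not isinstance(block, dict):
            diagnostics.append(f"section {section!r} must be a mapping")
            continue
        for key in block:
            if key not in allowed:
                diagnostics.append(f"unknown key: {section}.{key}")
    base = Path(path_or_dict).parent if not isinstance(path_or_dict, dict) else Path.cwd()
    inputs = config.get("inputs") or {}
    if isinstance(inputs, dict):
        for key, value in inputs.items():
            p = Path(value)
            if not p.is_absolute():
                p = base / p  # relative paths resolve against the config file
            if not p.exists():
                diagnostics.append(f"missing file: inputs.{key} = {value}")
    stages = config.get("stages") or {}
    if isinstance(stages, dict):
        if not stages.get("simulate", True) and not inputs:
            diagnostics.append("simulate disabled but no inputs given")
        if stages.get("scan", True) and not stages.get("roh", True):
            region = (config.get("scan") or {}).get("region")
            if not region:
                diagnostics.append(
                    "scan stage needs a region when the roh stage is disabled"
                )
    return diagnostics


def _parse_region(text: str) -> Segment:
    try:
        chrom, span = text.split(":")
        lo, hi = span.replace(",", "").split("-")
        return Segment(chrom, int(lo), int(hi), 0, 0)
    except (ValueError, InputError):
        raise InputError(f"cannot parse region {text!r}; expected chrom:start-end")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    return obj


def run_pipeline(config, out_dir=None, seed=None) -> dict:
    """Execute the enabled stages in dependency order; return the report.

    ``config`` is a YAML path or dict; ``out_dir``/``seed`` override the
    config.  A missing upstream artefact raises :class:`DependencyError`
    naming the stage.
    """
    config = load_config(config)
    seed = int(seed if seed is not None else config.get("seed", 0))
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "recmap_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = {name: True for name in STAGES}
    stages.update(config.get("stages") or {})

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.get("log_level", "INFO"))

    report: dict = {"seed": seed}
    input_digests: dict[str, str] = {}
    try:
        # -- simulate / ingest ------------------------------------------
        if stages.get("simulate", True):
            logger.info("stage simulate")
            sim_cfg = SimulationConfig(**{**(config.get("simulate") or {}), "seed": seed})
            panel_cfg = SequencePanelConfig(
                **{**(config.get("panel") or {}), "seed": seed}
            )
            study = simulate_study(sim_cfg, panel_cfg)
            from .simulate import write_fixture_bundle

            write_fixture_bundle(study, out / "simulate")
            geno = study.genotypes
            pheno = study.phenotypes
            panel = study.panel
            gene_model = study.gene_model
            reference = InMemoryReference({sim_cfg.chrom: study.reference_seq})
            report["simulate"] = {
                "n_individuals": int(geno.n_individuals),
                "n_markers": int(geno.n_markers),
                "causal_pos": int(study.causal_pos),
                "true_segment": list(study.true_segment),
            }
        else:
            inputs = config.get("inputs") or {}
            if "bundle" not in inputs:
                raise DependencyError(
                    "stage qc: simulate disabled and no inputs.bundle given"
                )
            bundle_dir = Path(inputs["bundle"])
            bundle = rio.read_fixture_bundle(bundle_dir)
            for f in sorted(bundle_dir.iterdir()):
                if f.is_file():
                    input_digests[f.name] = _sha256(f)
            geno = bundle["genotypes"]
            pheno = bundle["phenotypes"]
            panel = bundle["panel"]
            gene_model = bundle["gene_model"]
            reference = FastaReference(
                bundle_dir / bundle["manifest"]["files"]["reference"]
            )

        pheno = pheno.copy()
        pheno["id"] = pheno["id"].astype(str)

        # -- QC ---------------------------------------------------------
        if stages.get("qc", True):
            logger.info("stage qc")
            qc_cfg = QCConfig(**(config.get("qc") or {}))
            geno, qc_report = apply_qc(geno, qc_cfg)
            case_ids = [
                i for i in pheno.loc[pheno["case"], "id"] if i in set(map(str, geno.ids))
            ]
            control_ids = [
                i for i in pheno.loc[~pheno["case"], "id"] if i in set(map(str, geno.ids))
            ]
            if case_ids and control_ids:
                miss = differential_missingness(geno, case_ids, control_ids)
                qc_report.missingness_pvalues = miss
                qc_report.summary["min_missingness_p"] = float(miss["p"].min())
            qc_report.write(out / "qc")
            report["qc"] = qc_report.summary

        # -- GWAS -------------------------------------------------------
        anchor_idx = None
        grm = None
        scan_table = None
        if stages.get("gwas", True):
            logger.info("stage gwas")
            gwas_cfg = {"trait": "mra", "binary": True, "case_threshold": -20.0}
            gwas_cfg.update(config.get("gwas") or {})
            geno_ids = set(map(str, geno.ids))
            phenotyped = [i for i in pheno["id"] if i in geno_ids]
            rows = geno.individual_index(phenotyped)
            gsub = geno.subset(individuals=rows)
            psub = pheno.set_index("id").loc[phenotyped]
            grm = build_grm(gsub)
            if gwas_cfg["binary"]:
                cases = [
                    i
                    for i, v in zip(phenotyped, psub[gwas_cfg["trait"]])
                    if v < gwas_cfg["case_threshold"]
                ]
                controls = [i for i in phenotyped if i not in set(cases)]
                scan_table = case_control_scan(cases, controls, gsub, grm)
                # case_control_scan orders individuals cases-first
                reorder = gsub.individual_index(cases + controls)
                gsub = gsub.subset(individuals=reorder)
                psub = psub.loc[cases + controls]
                grm = build_grm(gsub)
            else:
                results = MixedModelGWAS(
                    psub[gwas_cfg["trait"]].to_numpy(float), gsub, grm
                ).fit()
                scan_table = results.table
            scan_table.to_csv(out / "gwas.tsv", sep="\t", index=False)
            top = scan_table.loc[scan_table["p"].idxmin()]
            anchor_idx = int(scan_table["p"].idxmin())
            report["gwas"] = {
                "n": int(len(psub)),
                "top_marker": str(top["marker"]),
                "top_chrom": str(top["chrom"]),
                "top_pos": int(top["pos"]),
                "top_p": float(top["p"]),
            }
            geno_for_roh = gsub
            pheno_for_roh = psub.reset_index()

        # -- autozygosity mapping --------------------------------------
        segment = None
        copies = None
        if stages.get("roh", True):
            if anchor_idx is None:
                raise DependencyError("stage roh: needs the gwas stage for an anchor")
            logger.info("stage roh")
            roh_cfg = {"max_het": 0, "max_missing": None, "match_threshold": 1.0}
            roh_cfg.update(config.get("roh") or {})
            case_mask = pheno_for_roh["case"].to_numpy(bool)
            case_ids = list(pheno_for_roh.loc[case_mask, "id"])
            hom = geno_for_roh.calls[:, anchor_idx] != 1
            nonmissing = geno_for_roh.calls[:, anchor_idx] != MISSING
            # cases homozygous (for either allele) at the anchor marker
            usable = [
                i
                for i in case_ids
                if hom[geno_for_roh.individual_index([i])[0]]
                and nonmissing[geno_for_roh.individual_index([i])[0]]
            ]
            if not usable:
                raise DependencyError(
                    "stage roh: no case is homozygous at the anchor marker"
                )
            case_rows = geno_for_roh.individual_index(usable)
            segment = shared_segment(
                geno_for_roh.calls[case_rows],
                anchor_idx,
                max_het=roh_cfg["max_het"],
                max_missing=roh_cfg["max_missing"],
                markers=geno_for_roh.markers,
            )
            hap_call = call_haplotype_copies(
                geno_for_roh, segment, usable, roh_cfg["match_threshold"]
            )
            copies = hap_call.copies
            sex = pheno_for_roh["sex"].to_numpy(dtype=object)
            counts_all = diplotype_counts(copies, "all")
            hwe_all = hwe_chisq(counts_all)
            slope, trend_p = carrier_trend(pheno_for_roh, copies)
            summary = fertility_summary(pheno_for_roh, copies)
            summary.to_csv(out / "fertility_summary.tsv", sep="\t", index=False)
            report["roh"] = {
                "n_cases_used": len(usable),
                "segment": {
                    "chrom": segment.chrom,
                    "start_bp": segment.start_bp,
                    "end_bp": segment.end_bp,
                    "n_markers": segment.n_markers,
                    "length_bp": segment.length_bp,
                },
                "diplotype_counts": {
                    "n0": counts_all.n0,
                    "n1": counts_all.n1,
                    "n2": counts_all.n2,
                },
                "haplotype_freq": counts_all.haplotype_freq,
                "hwe_chi2": hwe_all[0],
                "hwe_p": hwe_all[1],
                "carrier_trend_slope": slope,
                "carrier_trend_p": trend_p,
                "controls_homozygous": int(
                    ((copies == 2) & ~case_mask).sum()
                ),
                "fertility_summary": summary,
            }
            del sex

        # -- recessive scan --------------------------------------------
        retained_idx = None
        region_panel = None
        if stages.get("scan", True):
            logger.info("stage scan")
            scan_cfg = {"af_max": 0.10, "min_lc_het": 3, "mode": "conservative", "region": None}
            scan_cfg.update(config.get("scan") or {})
            if scan_cfg["region"]:
                region = _parse_region(scan_cfg["region"])
            elif segment is not None:
                region = segment
            else:
                raise DependencyError(
                    "stage scan: needs a region (roh stage output or scan.region)"
                )
            region_panel = restrict_to_region(panel, region)
            fcfg = FilterConfig(
                af_max=scan_cfg["af_max"],
                min_lc_het=scan_cfg["min_lc_het"],
                mode=scan_cfg["mode"],
            )
            if fcfg.mode == "strict":
                retained_idx = strict_filter(region_panel)
            else:
                retained_idx = conservative_filter(region_panel, fcfg)
            class_report = genotype_class_report(region_panel, retained_idx)
            class_report.to_csv(out / "scan_retained.tsv", sep="\t", index=False)
            vtypes = region_panel.variants["vtype"]
            report["scan"] = {
                "region_variants": int(region_panel.n_variants),
                "region_snps": int((vtypes == "SNP").sum()),
                "region_indels": int((vtypes == "INDEL").sum()),
                "retained": int(len(retained_idx)),
                "retained_snps": int(
                    (vtypes.iloc[retained_idx] == "SNP").sum()
                ),
                "retained_indels": int(
                    (vtypes.iloc[retained_idx] == "INDEL").sum()
                ),
            }

        # -- annotation -------------------------------------------------
        if stages.get("annotate", True):
            if retained_idx is None:
                raise DependencyError("stage annotate: needs the scan stage output")
            logger.info("stage annotate")
            partition = classify_retained(region_panel, retained_idx, gene_model)
            coding = region_panel.variants.iloc[partition["coding"]]
            annotated = annotate_variants(coding, gene_model, reference)
            annotated.to_csv(out / "annotated.tsv", sep="\t", index=False)
            stop_gains = annotated[annotated["consequence"] == "stop_gain"]
            report["annotate"] = {
                "n_coding": int(len(partition["coding"])),
                "n_noncoding": int(len(partition["noncoding"])),
                "consequences": annotated,
                "candidate": None
                if stop_gains.empty
                else _jsonify(stop_gains.iloc[0].to_dict()),
            }
    finally:
        logger.removeHandler(handler)
        handler.close()

    report = _jsonify(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.md", "w") as fh:
        fh.write(render_report_md(report))
    manifest = {
        "seed": seed,
        "version": __version__,
        "stages": {k: bool(stages.get(k, True)) for k in STAGES},
        "input_digests": input_digests,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def render_report_md(report: dict) -> str:
    lines = ["# Recessive-defect mapping report", ""]
    if "gwas" in report:
        g = report["gwas"]
        lines += [
            "## Association scan",
            f"Top marker **{g['top_marker']}** at {g['top_chrom']}:{g['top_pos']} "
            f"(P = {g['top_p']:.3g}, n = {g['n']}).",
            "",
        ]
    if "roh" in report:
        r = report["roh"]
        seg = r["segment"]
        lines += [
            "## Shared homozygous segment",
            f"{seg['chrom']}:{seg['start_bp']}-{seg['end_bp']} "
            f"({seg['length_bp'] / 1000:.0f} kb, {seg['n_markers']} markers) "
            f"shared by {r['n_cases_used']} cases.",
            f"Diplotype counts 0/1/2: {r['diplotype_counts']['n0']}/"
            f"{r['diplotype_counts']['n1']}/{r['diplotype_counts']['n2']} "
            f"(haplotype frequency {100 * r['haplotype_freq']:.1f}%, "
            f"HWE P = {r['hwe_p']:.3f}).",
            f"Controls homozygous for the segment: {r['controls_homozygous']}.",
            f"Carrier trend: {r['carrier_trend_slope']:.4f} per year "
            f"(P = {r['carrier_trend_p']:.2g}).",
            "",
        ]
    if "scan" in report:
        s = report["scan"]
        lines += [
            "## Recessive-compatibility scan",
            f"{s['region_variants']} region variants ({s['region_snps']} SNPs, "
            f"{s['region_indels']} INDELs); {s['retained']} retained "
            f"({s['retained_snps']} SNPs, {s['retained_indels']} INDELs).",
            "",
        ]
    if "annotate" in report:
        a = report["annotate"]
        lines += [
            "## Coding consequences",
            f"{a['n_coding']} coding / {a['n_noncoding']} non-coding retained variants.",
        ]
        if a.get("candidate"):
            c = a["candidate"]
            lines.append(
                f"Candidate causal variant: {c['gene']} {c['hgvs_c']} ({c['hgvs_p']}), "
                f"truncating {c['truncation']} residues."
            )
        lines.append("")
    return "\n".join(lines)
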
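"""Readers and writers for the pipeline's file formats.

Genotypes travel as a minimal VCF (GT:DS) or as a TSV dosage matrix with a
companion SNP map table; protein levels, annotation, covariates and
phenotypes as TSV; the simulation ground truth as a TSV edge list with a
JSON parameter sidecar. Every writer records the originating seed in a
comment header where one is known.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthio import CovariateTable, PhenotypeTable, ProteinPanel, SimTruth, SnpPanel

logger = logging.getLogger(__name__)

__all__ = [
    "write_snp_tsv",
    "read_snp_tsv",
    "write_vcf",
    "read_vcf",
    "write_protein_tsv",
    "read_protein_tsv",
    "write_covariates",
    "read_covariates",
    "write_phenotypes",
    "read_phenotypes",
    "write_truth",
    "read_truth",
    "load_inputs",
]


def _header(seed) -> str:
    return f"# seed={seed}\n" if seed is not None else ""


def write_snp_tsv(panel: SnpPanel, prefix, seed=None) -> None:
    prefix = Path(prefix)
    with open(f"{prefix}.dosage.tsv", "w") as fh:
        fh.write(_header(seed))
        panel.dosage_df().to_csv(fh, sep="\t", index_label="sample_id")
    snp_map = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "maf": panel.maf,
            "is_instrument": [s in set(panel.instrument_snps) for s in panel.snp_ids],
        }
    )
    with open(f"{prefix}.snps.tsv", "w") as fh:
        fh.write(_header(seed))
        snp_map.to_csv(fh, sep="\t", index=False)


def read_snp_tsv(prefix) -> SnpPanel:
    dos = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t", comment="#", index_col=0)
    snp_map = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", comment="#", dtype={"chrom": str})
    instruments = list(snp_map.loc[snp_map["is_instrument"], "snp_id"])
    return SnpPanel(
        sample_ids=list(dos.index),
        snp_ids=list(dos.columns),
        chrom=snp_map["chrom"].to_numpy(str),
        pos=snp_map["pos"].to_numpy(int),
        dosage=dos.to_numpy(float),
        maf=snp_map["maf"].to_numpy(float),
        instrument_snps=instruments,
    )


def write_vcf(panel: SnpPanel, path, seed=None) -> None:
    """Minimal VCF 4.2 with GT (rounded dosage) and DS (dosage) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##cpnet_seed={seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("##INFO=<ID=MAF,Number=1,Type=Float,Description=\"Minor allele frequency\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, sid in enumerate(panel.snp_ids):
            ds = panel.dosage[:, j]
            gt = np.clip(np.rint(ds), 0, 2).astype(int)
            cells = "\t".join(f"{gt_map[g]}:{d:.3f}" for g, d in zip(gt, ds))
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{sid}\tA\tG\t.\tPASS\t"
                f"MAF={panel.maf[j]:.4f}\tGT:DS\t{cells}\n"
            )


def read_vcf(path) -> SnpPanel:
    sample_ids: list = []
    snp_ids, chrom, pos, maf, rows = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            f = line.split("\t")
            chrom.append(f[0])
            pos.append(int(f[1]))
            snp_ids.append(f[2])
            info = dict(kv.split("=") for kv in f[7].split(";") if "=" in kv)
            fmt = f[8].split(":")
            ds_i = fmt.index("DS") if "DS" in fmt else None
            vals = []
            for cell in f[9:]:
                parts = cell.split(":")
                if ds_i is not None:
                    vals.append(float(parts[ds_i]))
                else:
                    vals.append(float(sum(int(x) for x in parts[0].replace("|", "/").split("/"))))
            rows.append(vals)
            maf.append(float(info.get("MAF", np.nan)))
    dosage = np.array(rows).T if rows else np.empty((len(sample_ids), 0))
    return SnpPanel(
        sample_ids, snp_ids, np.array(chrom), np.array(pos, dtype=int), dosage, np.array(maf)
    )


def write_protein_tsv(panel: ProteinPanel, prefix, seed=None) -> None:
    prefix = Path(prefix)
    with open(f"{prefix}.levels.tsv", "w") as fh:
        fh.write(_header(seed))
        panel.levels_df().to_csv(fh, sep="\t", index_label="sample_id")
    with open(f"{prefix}.annotation.tsv", "w") as fh:
        fh.write(_header(seed))
        panel.annotation.to_csv(fh, sep="\t", index=False)


def read_protein_tsv(prefix) -> ProteinPanel:
    lv = pd.read_csv(f"{prefix}.levels.tsv", sep="\t", comment="#", index_col=0)
    ann = pd.read_csv(f"{prefix}.annotation.tsv", sep="\t", comment="#", dtype={"chrom": str})
    required = {"aptamer_id", "gene", "chrom", "tss"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return ProteinPanel(list(lv.index), list(lv.columns), lv.to_numpy(float), ann)


def write_covariates(covs: CovariateTable, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        covs.table.to_csv(fh, sep="\t", index_label="sample_id")


def read_covariates(path) -> CovariateTable:
    table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    table.index.name = None
    return CovariateTable(table)


def write_phenotypes(ph: PhenotypeTable, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        spec = ";".join(f"{k}={v}" for k, v in ph.trait_spec.items())
        fh.write(f"# trait_spec={spec}\n")
        ph.table.to_csv(fh, sep="\t", index_label="sample_id")


def read_phenotypes(path) -> PhenotypeTable:
    spec = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# trait_spec="):
                for kv in line.strip().split("=", 1)[1].split(";"):
                    k, v = kv.split("=")
                    spec[k] = v
            if not line.startswith("#"):
                break
    table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    table.index.name = None
    if not spec:  # infer from column naming
        for c in table.columns:
            if c.startswith("time_"):
                spec[c[5:]] = "incident"
            elif c.startswith("event_"):
                continue
            elif set(table[c].dropna().unique()) <= {0, 1}:
                spec[c] = "prevalent"
            else:
                spec[c] = "continuous"
    return PhenotypeTable(table, spec)


def write_truth(truth: SimTruth, prefix, seed=None) -> None:
    prefix = Path(prefix)
    edges = pd.DataFrame(truth.true_edges, columns=["parent", "child", "beta"])
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write(_header(seed))
        edges.to_csv(fh, sep="\t", index=False)
    sidecar = {
        "seed": seed,
        "params": truth.params,
        "regulators": truth.regulators,
        "phenotype_effects": truth.phenotype_effects,
        "cis_effects": truth.cis_effects.to_dict(orient="list"),
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=float)


def read_truth(prefix) -> SimTruth:
    edges = pd.read_csv(f"{prefix}.edges.tsv", sep="\t", comment="#")
    with open(f"{prefix}.json") as fh:
        sidecar = json.load(fh)
    return SimTruth(
        true_edges=[tuple(r) for r in edges.itertuples(index=False)],
        regulators=sidecar["regulators"],
        cis_effects=pd.DataFrame(sidecar["cis_effects"]),
        phenotype_effects=sidecar["phenotype_effects"],
        params=sidecar.get("params", {}),
    )


def load_inputs(config: dict):
    """Load and sample-align all pipeline inputs declared in a config dict.

    Expects keys ``genotypes`` (prefix or .vcf path), ``proteins`` (prefix),
    ``covariates``, ``phenotypes`` (paths; optional). Samples present in
    every table are kept, mismatches dropped with a logged count; zero
    overlap is an error.
    """
    g = str(config["genotypes"])
    snps = read_vcf(g) if g.endswith(".vcf") else read_snp_tsv(g)
    proteins = read_protein_tsv(config["proteins"])
    covs = read_covariates(config["covariates"]) if config.get("covariates") else None
    phenos = read_phenotypes(config["phenotypes"]) if config.get("phenotypes") else None

    shared = [s for s in snps.sample_ids if s in set(proteins.sample_ids)]
    if covs is not None:
        shared = [s for s in shared if s in set(covs.table.index)]
    if phenos is not None:
        shared = [s for s in shared if s in set(phenos.table.index)]
    if not shared:
        raise ValueError("no overlapping samples across input tables")
    dropped = len(set(snps.sample_ids) | set(proteins.sample_ids)) - len(shared)
    if dropped:
        logger.info("dropped %d samples without complete data", dropped)

    gi = [snps.sample_ids.index(s) for s in shared]
    snps = SnpPanel(
        shared, snps.snp_ids, snps.chrom, snps.pos, snps.dosage[gi], snps.maf, snps.instrument_snps
    )
    pi = [proteins.sample_ids.index(s) for s in shared]
    proteins = ProteinPanel(
        shared, proteins.aptamer_ids, proteins.levels[pi], proteins.annotation
    )
    if covs is not None:
        covs = CovariateTable(covs.table.loc[shared])
    if phenos is not None:
        phenos = PhenotypeTable(phenos.table.loc[shared], phenos.trait_spec)
    return snps, proteins, covs, phenos
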
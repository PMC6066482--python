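"""File formats for the pipeline.

TSV with explicit headers is the interchange dialect between stages; every
file written by the pipeline starts with comment lines recording the
package version, a config hash and the seed, so a rerun with the same
config is byte-identical and auditable.  Genotypes additionally round-trip
as a PLINK-style PED/MAP pair; voxel maps round-trip as a packed ``.npz``
or as one NIfTI file per subject and map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import NodeAtlas, edge_label, parse_edge_label
from .connectome import ConnectivityRecord, EdgeVoxelData
from .popgen import MISSING, SNP, GenotypeTable
from .simulate import Truth


def provenance_header(config_hash: str = "", seed: int | None = None) -> str:
    parts = [f"# rewardnet {__version__}"]
    if config_hash:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    header: str = "",
    index: bool = False,
    float_format: str = "%.10g",
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# -- subjects ---------------------------------------------------------------

def write_subjects(subjects: pd.DataFrame, path: str | Path, header: str = "") -> None:
    write_tsv(subjects.reset_index(), path, header=header)


def read_subjects(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, index_col="subject")


# -- genotypes --------------------------------------------------------------

def write_genotypes_tsv(table: GenotypeTable, path: str | Path, header: str = "") -> None:
    """Long dialect: subject, snp, allele1, allele2 (missing ``0 0``)."""
    rows = []
    for subj in table.subjects:
        for snp in table.snps:
            g = table.calls.at[subj, snp.snp_id]
            a1, a2 = (g[0], g[1])
            rows.append({"subject": subj, "snp": snp.snp_id,
                         "allele1": a1, "allele2": a2,
                         "risk_allele": snp.risk_allele})
    write_tsv(pd.DataFrame(rows), path, header=header)


def read_genotypes_tsv(path: str | Path) -> GenotypeTable:
    df = read_tsv(path)
    subjects = list(dict.fromkeys(df["subject"]))
    snps = []
    calls = {}
    for snp_id, grp in df.groupby("snp", sort=False):
        geno = (grp["allele1"].astype(str) + grp["allele2"].astype(str)).to_numpy()
        alleles = sorted(set("".join(g for g in geno if g != MISSING)))
        if len(alleles) != 2:
            raise ValueError(f"{snp_id}: expected two alleles, saw {alleles}")
        risk = str(grp["risk_allele"].iloc[0]) if "risk_allele" in grp else alleles[1]
        snps.append(SNP(snp_id, allele_a=alleles[0], allele_b=alleles[1],
                        risk_allele=risk))
        norm = ["".join(sorted(g)) if g != MISSING else MISSING for g in geno]
        calls[snp_id] = pd.Series(norm, index=list(grp["subject"]))
    return GenotypeTable(subjects=subjects, snps=snps,
                         calls=pd.DataFrame(calls).loc[subjects])


def write_ped_map(
    table: GenotypeTable,
    groups: pd.Series,
    ped_path: str | Path,
    map_path: str | Path,
    chromosome: int = 4,
) -> None:
    """PLINK text PED/MAP pair; phenotype 2 = case (HA), 1 = control."""
    ped_path, map_path = Path(ped_path), Path(map_path)
    ped_path.parent.mkdir(parents=True, exist_ok=True)
    with open(map_path, "w") as fh:
        for k, snp in enumerate(table.snps):
            fh.write(f"{chromosome}\t{snp.snp_id}\t0\t{1000 * (k + 1)}\n")
    with open(ped_path, "w") as fh:
        for subj in table.subjects:
            pheno = 2 if groups.get(subj) == "HA" else 1
            fields = [subj, subj, "0", "0", "0", str(pheno)]
            for snp in table.snps:
                g = table.calls.at[subj, snp.snp_id]
                fields.extend([g[0], g[1]])
            fh.write("\t".join(fields) + "\n")


def read_ped_map(
    ped_path: str | Path, map_path: str | Path,
    risk_alleles: dict[str, str] | None = None,
) -> tuple[GenotypeTable, pd.Series]:
    """Read a PED/MAP pair; returns the table and the case/control labels."""
    snp_ids = [line.split()[1] for line in open(map_path) if line.strip()]
    subjects, phenos, geno_rows = [], [], []
    for line in open(ped_path):
        if not line.strip():
            continue
        f = line.split()
        subjects.append(f[1])
        phenos.append("HA" if f[5] == "2" else "HC")
        alleles = f[6:]
        if len(alleles) != 2 * len(snp_ids):
            raise ValueError(f"subject {f[1]}: expected {2 * len(snp_ids)} "
                             f"allele fields, got {len(alleles)}")
        geno_rows.append(["".join(sorted(alleles[2 * k: 2 * k + 2]))
                          for k in range(len(snp_ids))])
    calls = pd.DataFrame(geno_rows, index=subjects, columns=snp_ids)
    calls = calls.replace({"00": MISSING})
    snps = []
    for sid in snp_ids:
        observed = sorted(set("".join(g for g in calls[sid] if g != MISSING)))
        if len(observed) != 2:
            raise ValueError(f"{sid}: expected two alleles, saw {observed}")
        risk = (risk_alleles or {}).get(sid, observed[1])
        snps.append(SNP(sid, allele_a=observed[0], allele_b=observed[1],
                        risk_allele=risk))
    table = GenotypeTable(subjects=subjects, snps=snps, calls=calls)
    return table, pd.Series(phenos, index=subjects, name="group")


# -- edge strengths and matrices -------------------------------------------

def write_edge_strengths(
    records: list[ConnectivityRecord], atlas: NodeAtlas,
    path: str | Path, header: str = "",
) -> None:
    """Long format: subject, node_i, node_j, strength — one row per edge."""
    rows = []
    for rec in records:
        for e in atlas.edges():
            rows.append({"subject": rec.subject, "node_i": e[0],
                         "node_j": e[1], "strength": rec.strength(e)})
    write_tsv(pd.DataFrame(rows), path, header=header)


def read_edge_strengths(path: str | Path) -> pd.DataFrame:
    """Wide subjects x edges table; columns are ``node_i--node_j`` labels."""
    df = read_tsv(path)
    df["edge"] = df["node_i"] + "--" + df["node_j"]
    wide = df.pivot(index="subject", columns="edge", values="strength")
    ordered = list(dict.fromkeys(df["edge"]))
    return wide[ordered]


def write_matrix(
    matrix: np.ndarray, labels: list[str], path: str | Path, header: str = ""
) -> None:
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    write_tsv(df.reset_index(names="node"), path, header=header)


# -- voxel maps -------------------------------------------------------------

def write_voxel_npz(
    voxel_data: dict[tuple[str, str], EdgeVoxelData], path: str | Path,
    compress: bool = True,
) -> None:
    """All edges' streamline maps plus the shared FA maps, one packed file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    edges = sorted(voxel_data)
    first = voxel_data[edges[0]]
    arrays = {"fa": first.fa, "subjects": np.array(first.subjects)}
    arrays["edges"] = np.array([edge_label(e) for e in edges])
    for e in edges:
        arrays[f"stream_{edge_label(e)}"] = voxel_data[e].streamline
    (np.savez_compressed if compress else np.savez)(path, **arrays)


def read_voxel_npz(path: str | Path) -> dict[tuple[str, str], EdgeVoxelData]:
    with np.load(path, allow_pickle=False) as z:
        subjects = [str(s) for s in z["subjects"]]
        fa = z["fa"]
        out = {}
        for lab in z["edges"]:
            e = parse_edge_label(str(lab))
            out[e] = EdgeVoxelData(
                edge=e, subjects=subjects,
                streamline=z[f"stream_{lab}"], fa=fa,
            )
    return out


def write_voxel_nifti(
    voxel_data: dict[tuple[str, str], EdgeVoxelData], out_dir: str | Path
) -> None:
    """One NIfTI per subject FA map and per subject-edge streamline map."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    edges = sorted(voxel_data)
    first = voxel_data[edges[0]]
    for k, subj in enumerate(first.subjects):
        nib.save(nib.Nifti1Image(np.asarray(first.fa[k], dtype=np.float32), affine),
                 out_dir / f"{subj}_fa.nii.gz")
    for e in edges:
        data = voxel_data[e]
        for k, subj in enumerate(data.subjects):
            nib.save(
                nib.Nifti1Image(np.asarray(data.streamline[k], dtype=np.float32),
                                affine),
                out_dir / f"{subj}_{edge_label(e)}_stream.nii.gz",
            )


# -- truth record -----------------------------------------------------------

def write_truth(truth: Truth, path: str | Path, header: str = "") -> None:
    payload = {
        "affected_edges": {edge_label(e): v for e, v in truth.affected_edges.items()},
        "genetic_effect": (
            None if truth.genetic_effect is None else {
                "snp_id": truth.genetic_effect.snp_id,
                "beta": truth.genetic_effect.beta,
                "interaction": truth.genetic_effect.interaction,
            }
        ),
        "mediation": {
            "b": truth.mediation.b, "c_prime": truth.mediation.c_prime,
            "noise_sd": truth.mediation.noise_sd,
        },
        "edge_noise_sd": truth.edge_noise_sd,
        "indirect_effect": truth.indirect_effect,
        "region_shape": list(truth.region_shape),
        "region_origins": {
            edge_label(e): list(o) for e, o in truth.region_origins.items()
        },
    }
    if header:
        payload["provenance"] = header.lstrip("# ")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
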
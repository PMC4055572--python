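"""Text-format readers and writers.

Supported formats are all plain text: PLINK transposed genotypes
(.tped/.tfam) with a companion .map carrying both cM and bp positions,
frequency tables as tidy CSV (population, locus, freq, n), true ancestry
tracks as a BED-like table, ADMIXTURE-convention Q matrices (whitespace
table plus a labels file), population coordinates CSV, drift-tree/topology
JSON, and group assignments YAML.

Alleles are coded "1" (reference, our 0) and "2" (alternate, our 1),
following PLINK numeric-allele convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .admixsim import AncestryTrack
from .sources import DriftTree, FrequencyTable, GeneticMap, HaplotypePanel

__all__ = [
    "write_tped",
    "read_tped",
    "write_map",
    "read_map",
    "write_frequency_csv",
    "read_frequency_csv",
    "write_tracks",
    "read_tracks",
    "read_qmatrix",
    "write_tree_json",
    "read_tree_json",
    "read_topology_json",
    "read_groups_yaml",
    "read_coordinates_csv",
]


def write_tped(
    prefix: str | Path,
    genetic_map: GeneticMap,
    haplotype_pairs: np.ndarray,
    sample_ids: list[str],
    population: str = "POP",
) -> None:
    """Write diploid data as .tped/.tfam.

    ``haplotype_pairs`` is (n_individuals, 2, n_loci) with 0/1 alleles.
    """
    prefix = Path(prefix)
    hp = np.asarray(haplotype_pairs)
    n_ind = hp.shape[0]
    if len(sample_ids) != n_ind:
        raise ValueError("sample_ids must match individual count")
    codes = hp + 1  # 0/1 -> 1/2
    with open(prefix.with_suffix(".tped"), "w") as fh:
        for l in range(genetic_map.n_loci):
            cm = genetic_map.position_morgans[l] * 100.0
            fields = [
                str(genetic_map.chromosome[l]),
                str(genetic_map.locus_id[l]),
                f"{cm:.6f}",
                str(genetic_map.position_bp[l]),
            ]
            for i in range(n_ind):
                fields += [str(codes[i, 0, l]), str(codes[i, 1, l])]
            fh.write(" ".join(fields) + "\n")
    with open(prefix.with_suffix(".tfam"), "w") as fh:
        for sid in sample_ids:
            fh.write(f"{population} {sid} 0 0 0 -9\n")


def read_tped(prefix: str | Path) -> tuple[GeneticMap, np.ndarray, pd.DataFrame]:
    """Read .tped/.tfam; returns (map, (n_ind, 2, n_loci) alleles, sample frame)."""
    prefix = Path(prefix)
    tfam = pd.read_csv(
        prefix.with_suffix(".tfam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    chroms, ids, cms, bps, rows = [], [], [], [], []
    with open(prefix.with_suffix(".tped")) as fh:
        for line in fh:
            parts = line.split()
            chroms.append(int(parts[0]))
            ids.append(parts[1])
            cms.append(float(parts[2]))
            bps.append(int(parts[3]))
            rows.append(np.array(parts[4:], dtype=np.int8) - 1)
    alleles = np.stack(rows, axis=-1)  # (2*n_ind, n_loci) interleaved
    n_ind = len(tfam)
    hp = alleles.reshape(n_ind, 2, -1)
    gmap = GeneticMap(
        locus_id=np.asarray(ids, dtype=object),
        chromosome=np.asarray(chroms),
        position_morgans=np.asarray(cms) / 100.0,
        position_bp=np.asarray(bps),
    )
    return gmap, hp, tfam


def write_map(path: str | Path, genetic_map: GeneticMap) -> None:
    """PLINK .map with chromosome, id, cM and bp columns."""
    with open(path, "w") as fh:
        for l in range(genetic_map.n_loci):
            fh.write(
                f"{genetic_map.chromosome[l]} {genetic_map.locus_id[l]} "
                f"{genetic_map.position_morgans[l] * 100.0:.6f} "
                f"{genetic_map.position_bp[l]}\n"
            )


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "bp"])
    return GeneticMap(
        locus_id=df["id"].to_numpy(dtype=object),
        chromosome=df["chrom"].to_numpy(),
        position_morgans=df["cm"].to_numpy(dtype=float) / 100.0,
        position_bp=df["bp"].to_numpy(),
    )


def write_frequency_csv(path: str | Path, table: FrequencyTable) -> None:
    table.to_frame().to_csv(path, index=False)


def read_frequency_csv(path: str | Path) -> FrequencyTable:
    return FrequencyTable.from_frame(pd.read_csv(path))


def write_tracks(path: str | Path, track: AncestryTrack, labels: tuple[str, str] = ("A", "B")) -> None:
    """True ancestry tracks as a BED-like text table (one row per segment)."""
    seg = track.segments()
    seg = seg.assign(ancestry=seg["ancestry"].map({0: labels[0], 1: labels[1]}))
    seg.to_csv(path, sep="\t", index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_qmatrix(q_path: str | Path, labels_path: str | Path):
    """ADMIXTURE-convention .Q whitespace table plus a one-label-per-line file.

    Returns (population labels array, proportion matrix); wrap into
    :class:`~hoa_admixkit.popstruct.QMatrix` with component names of choice.
    """
    q = np.loadtxt(q_path, ndmin=2)
    labels = [line.strip() for line in open(labels_path) if line.strip()]
    if len(labels) != q.shape[0]:
        raise ValueError("labels file does not match Q matrix rows")
    return np.asarray(labels, dtype=object), q


def write_tree_json(path: str | Path, tree: DriftTree) -> None:
    Path(path).write_text(json.dumps(tree.to_dict(), indent=2) + "\n")


def read_tree_json(path: str | Path) -> DriftTree:
    return DriftTree.from_dict(json.loads(Path(path).read_text()))


def read_topology_json(path: str | Path) -> dict:
    """Tree-model topology: nested {"name", "children"} mapping."""
    return json.loads(Path(path).read_text())


def read_groups_yaml(path: str | Path) -> Mapping[str, str]:
    """population -> group assignment."""
    data = yaml.safe_load(Path(path).read_text())
    return {str(k): str(v) for k, v in data.items()}


def read_coordinates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"population", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinates CSV needs columns {sorted(required)}")
    return df


def panel_to_haplotype_pairs(panel: HaplotypePanel, pairs: np.ndarray) -> np.ndarray:
    """(n_ind, 2, n_loci) view of a haploid panel given a diploid pairing."""
    return panel.haplotypes[pairs]
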
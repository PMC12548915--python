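"""Reading, merging and splitting interaction tables.

Formats (tab- or comma-delimited text with headers):

* DFI tables: ``drug_id, drug_smiles, food_id, food_smiles, label`` with
  binary labels;
* DCI tables: ``compound_id`` plus ten columns ``<isoenzyme>_<type>``
  (e.g. ``cyp3a4_substrate``) with values ``1``, ``0`` or ``NA``;
* split specifications: ``compound_id, cluster_id, partition`` plus a
  ``#``-prefixed provenance header.

Cold splits confine whole Butina clusters of the cold-side compounds to a
single partition, so no drug (cold-drug) or food (cold-food) compound is
shared between train/valid/test.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit import Chem

from .cyp import INTERACTION_TYPES, ISOENZYMES
from .featurize import FP_RADIUS, N_BITS, CompoundRecord, CompoundRole, canonicalize_smiles
from .losses import DciLabelMatrix

__all__ = [
    "DfiExample",
    "DatasetStatistics",
    "SplitSpec",
    "read_dfi_table",
    "write_dfi_table",
    "read_dci_table",
    "write_dci_table",
    "dataset_statistics",
    "combine_statistics",
    "integrate_sources",
    "integrate_dci_sources",
    "dci_cell_counts",
    "combine_dci_counts",
    "butina_clusters",
    "cold_split",
    "read_split_spec",
    "DCI_COLUMNS",
]

DCI_COLUMNS = tuple(f"{iso.lower()}_{typ}" for typ in INTERACTION_TYPES for iso in ISOENZYMES)


@dataclass(frozen=True)
class DfiExample:
    drug: CompoundRecord
    food: CompoundRecord
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class DatasetStatistics:
    n_drugs: int
    n_foods: int
    n_pairs: int
    n_pos: int
    n_neg: int

    def __post_init__(self):
        if self.n_pairs != self.n_pos + self.n_neg:
            raise ValueError("n_pairs must equal n_pos + n_neg")

    @property
    def possible_pairs(self) -> int:
        return self.n_drugs * self.n_foods

    @property
    def sparsity_pct(self) -> float:
        """Observed pairs as a percentage of the full drug x food grid."""
        return 100.0 * self.n_pairs / self.possible_pairs if self.possible_pairs else 0.0


@dataclass(frozen=True)
class SplitSpec:
    mode: str  # "cold_drug" | "cold_food"
    cluster_of: dict[str, int]  # cold-side compound id -> cluster id
    partition_of: dict[int, str]  # cluster id -> "train" | "valid" | "test"
    seed: int
    fractions: tuple[float, float, float]
    distance_cutoff: float = 0.6

    def partition_of_compound(self, compound_id: str) -> str:
        return self.partition_of[self.cluster_of[compound_id]]

    def assign(self, examples: list[DfiExample]) -> dict[str, list[DfiExample]]:
        """Route each example to its cold-side compound's partition."""
        out: dict[str, list[DfiExample]] = {"train": [], "valid": [], "test": []}
        for ex in examples:
            cold_id = ex.drug.id if self.mode == "cold_drug" else ex.food.id
            out[self.partition_of_compound(cold_id)].append(ex)
        return out

    def leakage(self, examples: list[DfiExample]) -> int:
        """Number of cold-side compounds appearing in more than one partition."""
        seen: dict[str, set[str]] = {}
        for ex in examples:
            cold_id = ex.drug.id if self.mode == "cold_drug" else ex.food.id
            seen.setdefault(cold_id, set()).add(self.partition_of_compound(cold_id))
        return sum(1 for parts in seen.values() if len(parts) > 1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# mode={self.mode} cutoff={self.distance_cutoff} seed={self.seed} "
                f"fractions={','.join(str(f) for f in self.fractions)}\n"
            )
            fh.write("compound_id\tcluster_id\tpartition\n")
            for cid in sorted(self.cluster_of):
                cl = self.cluster_of[cid]
                fh.write(f"{cid}\t{cl}\t{self.partition_of[cl]}\n")


def read_split_spec(path) -> SplitSpec:
    meta: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    cluster_of = dict(zip(df["compound_id"].astype(str), df["cluster_id"].astype(int)))
    partition_of = dict(zip(df["cluster_id"].astype(int), df["partition"].astype(str)))
    fractions = tuple(float(x) for x in meta.get("fractions", "0.72,0.06,0.22").split(","))
    return SplitSpec(
        mode=meta.get("mode", "cold_drug"),
        cluster_of=cluster_of,
        partition_of=partition_of,
        seed=int(meta.get("seed", 0)),
        fractions=fractions,  # type: ignore[arg-type]
        distance_cutoff=float(meta.get("cutoff", 0.6)),
    )


# ---------------------------------------------------------------------------
# table readers / writers
# ---------------------------------------------------------------------------

_DFI_COLUMNS = ("drug_id", "drug_smiles", "food_id", "food_smiles", "label")


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def read_dfi_table(path) -> list[DfiExample]:
    """Validated DFI examples; duplicate canonical pairs are collapsed and
    conflicting duplicate labels raise."""
    df = _read_delimited(path)
    missing = [c for c in _DFI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DFI table {path} is missing columns: {missing}")
    examples: dict[tuple[str, str], DfiExample] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        if row.label not in ("0", "1"):
            raise ValueError(f"row {row_number}: label must be 0 or 1, got {row.label!r}")
        try:
            d_smiles = canonicalize_smiles(row.drug_smiles)
            f_smiles = canonicalize_smiles(row.food_smiles)
        except ValueError as exc:
            raise ValueError(f"row {row_number}: {exc}") from exc
        key = (d_smiles, f_smiles)
        ex = DfiExample(
            drug=CompoundRecord(id=str(row.drug_id), smiles=d_smiles, role=CompoundRole.DRUG),
            food=CompoundRecord(id=str(row.food_id), smiles=f_smiles, role=CompoundRole.FOOD),
            label=int(row.label),
        )
        if key in examples:
            if examples[key].label != ex.label:
                raise ValueError(
                    f"conflicting labels for duplicate pair drug={row.drug_id} food={row.food_id}"
                )
            continue
        examples[key] = ex
    return list(examples.values())


def write_dfi_table(examples: list[DfiExample], path) -> None:
    df = pd.DataFrame(
        {
            "drug_id": [e.drug.id for e in examples],
            "drug_smiles": [e.drug.smiles for e in examples],
            "food_id": [e.food.id for e in examples],
            "food_smiles": [e.food.smiles for e in examples],
            "label": [e.label for e in examples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_dci_table(path) -> dict[str, DciLabelMatrix]:
    """Per-compound three-valued annotation matrices."""
    df = _read_delimited(path)
    if "compound_id" not in df.columns:
        raise ValueError(f"DCI table {path} is missing the compound_id column")
    unknown = [c for c in df.columns if c not in ("compound_id",) + DCI_COLUMNS]
    if unknown:
        raise ValueError(f"DCI table {path} has unknown columns: {unknown}")
    out: dict[str, DciLabelMatrix] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        values = np.full((len(INTERACTION_TYPES), len(ISOENZYMES)), np.nan)
        for t, typ in enumerate(INTERACTION_TYPES):
            for j, iso in enumerate(ISOENZYMES):
                col = f"{iso.lower()}_{typ}"
                if col not in df.columns:
                    continue
                raw = getattr(row, col)
                if raw in ("", "NA", "nan", "NaN"):
                    continue
                if raw not in ("0", "1"):
                    raise ValueError(f"row {row_number}: value for {col} must be 1, 0 or NA, got {raw!r}")
                values[t, j] = float(raw)
        out[str(row.compound_id)] = DciLabelMatrix(values)
    return out


def write_dci_table(labels: dict[str, DciLabelMatrix], path) -> None:
    rows = []
    for cid, mat in labels.items():
        row: dict[str, str] = {"compound_id": cid}
        for t, typ in enumerate(INTERACTION_TYPES):
            for j, iso in enumerate(ISOENZYMES):
                v = mat.values[t, j]
                row[f"{iso.lower()}_{typ}"] = "NA" if not np.isfinite(v) else str(int(v))
        rows.append(row)
    pd.DataFrame(rows, columns=("compound_id",) + DCI_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# statistics and integration
# ---------------------------------------------------------------------------


def dataset_statistics(examples: list[DfiExample]) -> DatasetStatistics:
    if not examples:
        raise ValueError("empty example list")
    drugs = {e.drug.smiles for e in examples}
    foods = {e.food.smiles for e in examples}
    n_pos = sum(e.label for e in examples)
    return DatasetStatistics(
        n_drugs=len(drugs),
        n_foods=len(foods),
        n_pairs=len(examples),
        n_pos=n_pos,
        n_neg=len(examples) - n_pos,
    )


def combine_statistics(
    per_source: list[DatasetStatistics], n_drugs: int, n_foods: int
) -> DatasetStatistics:
    """Merged statistics for pairwise-disjoint sources.

    Pair counts add; the merged unique-compound counts cannot be derived from
    per-source counts (compounds overlap between sources) and are passed in.
    """
    return DatasetStatistics(
        n_drugs=n_drugs,
        n_foods=n_foods,
        n_pairs=sum(s.n_pairs for s in per_source),
        n_pos=sum(s.n_pos for s in per_source),
        n_neg=sum(s.n_neg for s in per_source),
    )


def integrate_sources(
    tables: list[tuple[str, list[DfiExample]]], positive_wins: bool = False
) -> tuple[list[DfiExample], dict[str, DatasetStatistics]]:
    """Union DFI tables on canonical compound pairs.

    Conflicting labels for the same pair raise unless ``positive_wins``.
    Returns the merged examples and per-source plus merged statistics.
    """
    if not tables:
        raise ValueError("need at least one source")
    merged: dict[tuple[str, str], DfiExample] = {}
    stats: dict[str, DatasetStatistics] = {}
    for name, examples in tables:
        stats[name] = dataset_statistics(examples)
        for ex in examples:
            key = (ex.drug.smiles, ex.food.smiles)
            if key in merged and merged[key].label != ex.label:
                if positive_wins:
                    if ex.label == 1:
                        merged[key] = ex
                    continue
                raise ValueError(
                    f"conflicting labels across sources for pair drug={ex.drug.id} food={ex.food.id}"
                )
            merged.setdefault(key, ex)
    out = list(merged.values())
    stats["merged"] = dataset_statistics(out)
    return out, stats


def integrate_dci_sources(
    tables: list[tuple[str, dict[str, DciLabelMatrix]]]
) -> dict[str, DciLabelMatrix]:
    """Union DCI annotation maps cell-wise; conflicting cells raise."""
    merged: dict[str, np.ndarray] = {}
    for name, table in tables:
        for cid, mat in table.items():
            if cid not in merged:
                merged[cid] = mat.values.copy()
                continue
            cur = merged[cid]
            both = np.isfinite(cur) & np.isfinite(mat.values)
            if np.any(cur[both] != mat.values[both]):
                raise ValueError(f"conflicting DCI labels for compound {cid} in source {name}")
            take = np.isfinite(mat.values) & ~np.isfinite(cur)
            cur[take] = mat.values[take]
    return {cid: DciLabelMatrix(arr) for cid, arr in merged.items()}


def dci_cell_counts(table: dict[str, DciLabelMatrix]) -> np.ndarray:
    """Number of annotated compounds per (interaction type, isoenzyme) cell."""
    counts = np.zeros((len(INTERACTION_TYPES), len(ISOENZYMES)), dtype=int)
    for mat in table.values():
        counts += np.isfinite(mat.values).astype(int)
    return counts


def combine_dci_counts(per_source: list[np.ndarray]) -> np.ndarray:
    """Cell counts of a union of compound-disjoint annotation sources."""
    return np.sum(per_source, axis=0)


# ---------------------------------------------------------------------------
# clustering and cold splits
# ---------------------------------------------------------------------------

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=N_BITS)


def _fingerprints(compounds: list[CompoundRecord]):
    fps = []
    for c in compounds:
        mol = Chem.MolFromSmiles(canonicalize_smiles(c.smiles))
        fps.append(_fp_generator.GetFingerprint(mol))
    return fps


def butina_clusters(
    compounds: list[CompoundRecord], distance_cutoff: float = 0.6
) -> dict[str, int]:
    """Sphere-exclusion (Butina) clustering on fingerprint Tanimoto distance.

    Neighborhoods are pairs at distance <= cutoff.  Compounds are visited in
    order of decreasing neighbor count (ties: lower input index first); an
    unassigned compound starts a new cluster containing itself and all its
    still-unassigned neighbors.
    """
    if not compounds:
        raise ValueError("no compounds to cluster")
    if not 0.0 < distance_cutoff < 1.0:
        raise ValueError("distance cutoff must lie in (0, 1)")
    fps = _fingerprints(compounds)
    n = len(fps)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
            for off, s in enumerate(sims):
                j = i + 1 + off
                if 1.0 - s <= distance_cutoff:
                    neighbors[i].append(j)
                    neighbors[j].append(i)
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), i))
    assigned = np.full(n, -1, dtype=int)
    next_cluster = 0
    for i in order:
        if assigned[i] >= 0:
            continue
        assigned[i] = next_cluster
        for j in neighbors[i]:
            if assigned[j] < 0:
                assigned[j] = next_cluster
        next_cluster += 1
    return {c.id: int(assigned[k]) for k, c in enumerate(compounds)}


def cold_split(
    examples: list[DfiExample],
    mode: str = "cold_drug",
    fractions: tuple[float, float, float] = (0.72, 0.06, 0.22),
    distance_cutoff: float = 0.6,
    seed: int = 0,
) -> SplitSpec:
    """Assign whole cold-side clusters to train/valid/test.

    Clusters are taken largest-first (ties shuffled by the seed) and each is
    routed to the partition with the largest remaining deficit relative to
    its target example count.
    """
    if mode not in ("cold_drug", "cold_food"):
        raise ValueError("mode must be cold_drug or cold_food")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    side = "drug" if mode == "cold_drug" else "food"
    by_id: dict[str, CompoundRecord] = {}
    example_count: dict[str, int] = {}
    for ex in examples:
        comp = getattr(ex, side)
        by_id[comp.id] = comp
        example_count[comp.id] = example_count.get(comp.id, 0) + 1
    compounds = [by_id[cid] for cid in sorted(by_id)]
    cluster_of = butina_clusters(compounds, distance_cutoff)
    cluster_sizes: dict[int, int] = {}
    for cid, cl in cluster_of.items():
        cluster_sizes[cl] = cluster_sizes.get(cl, 0) + example_count[cid]
    rng = np.random.Generator(np.random.PCG64(seed))
    clusters = list(cluster_sizes)
    rng.shuffle(clusters)
    clusters.sort(key=lambda cl: -cluster_sizes[cl])  # stable: ties keep shuffled order
    total = sum(cluster_sizes.values())
    names = ("train", "valid", "test")
    targets = {p: f * total for p, f in zip(names, fractions)}
    filled = {p: 0 for p in names}
    partition_of: dict[int, str] = {}
    for cl in clusters:
        deficits = {p: targets[p] - filled[p] for p in names}
        best = max(names, key=lambda p: deficits[p])
        partition_of[cl] = best
        filled[best] += cluster_sizes[cl]
    # repair: when clusters are few, a small-fraction partition can end up
    # empty although enough clusters exist — move a smallest cluster over
    for p in names:
        if filled[p] > 0:
            continue
        donors = [
            cl
            for cl, q in partition_of.items()
            if sum(1 for c2 in partition_of if partition_of[c2] == q) > 1
        ]
        if donors:
            move = min(donors, key=lambda cl: (cluster_sizes[cl], cl))
            filled[partition_of[move]] -= cluster_sizes[move]
            partition_of[move] = p
            filled[p] += cluster_sizes[move]
    empty = [p for p in names if filled[p] == 0]
    if empty:
        raise ValueError(
            f"partition(s) {empty} received no examples; use more data, a smaller "
            f"distance cutoff, or different fractions"
        )
    return SplitSpec(
        mode=mode,
        cluster_of=cluster_of,
        partition_of=partition_of,
        seed=seed,
        fractions=tuple(fractions),
        distance_cutoff=distance_cutoff,
    )
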
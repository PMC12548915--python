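"""Attention-based interpretation of trained models.

For a drug-food pair, one eval-mode forward pass yields, per compound and
per attention head, a 5 x (n + n_pseudo) attention matrix over that
compound's real substructures plus the shared pseudo-substructures.  The
per-isoenzyme DCI score is the row mass on the real columns; the most
attended real substructures are mapped back to atom sets through the
fingerprint bit provenance, which is how substructure-level heatmaps and
atom highlights are produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .cyp import INTERACTION_TYPES, ISOENZYMES
from .featurize import SubstructureSet, compute_substructures, build_molecular_graph, map_bits_to_atoms
from .model import AttentionTensor, DFIModel, DciScoreMatrix, ForwardTrace

__all__ = ["ExplanationReport", "explain_pair", "top_substructures", "write_report"]


@dataclass(frozen=True)
class ExplanationReport:
    compound_id: str
    smiles: str
    substructures: SubstructureSet
    attention: AttentionTensor  # (heads, 5, n + n_pseudo)
    dci: DciScoreMatrix  # (2, 5) = attention mass on real columns, heads 0-1
    top_substructures: dict[tuple[int, str], list[tuple[int, float, frozenset[int]]]]
    # (head, isoenzyme) -> [(bit, weight, atom indices)] descending by weight


def top_substructures(
    attention: AttentionTensor,
    substructures: SubstructureSet,
    smiles: str,
    k: int = 3,
) -> dict[tuple[int, str], list[tuple[int, float, frozenset[int]]]]:
    """Per (head, isoenzyme): the k highest-weighted real substructure bits.

    Ties are broken by lower bit index; atom sets come from the fingerprint
    provenance.  Returns fewer than k entries when the compound has fewer
    real substructures.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = attention.n
    bits = substructures.bits
    atom_map = map_bits_to_atoms(substructures, smiles, list(bits))
    out: dict[tuple[int, str], list[tuple[int, float, frozenset[int]]]] = {}
    for head in range(attention.weights.shape[0]):
        for j, iso in enumerate(ISOENZYMES):
            row = attention.weights[head, j, :n]
            order = sorted(range(n), key=lambda i: (-row[i], bits[i]))[:k]
            out[(head, iso)] = [
                (bits[i], float(row[i]), frozenset(atom_map[bits[i]])) for i in order
            ]
    return out


def _report(compound_id: str, smiles: str, s: SubstructureSet, attention, dci, k=3):
    return ExplanationReport(
        compound_id=compound_id,
        smiles=smiles,
        substructures=s,
        attention=attention,
        dci=dci,
        top_substructures=top_substructures(attention, s, smiles, k=k),
    )


def explain_pair(
    model: DFIModel, drug_smiles: str, food_smiles: str, k: int = 3
) -> tuple[ExplanationReport, ExplanationReport, float]:
    """Explanation reports for both compounds plus the interaction score,
    all from a single eval-mode forward trace."""
    ds = compute_substructures(drug_smiles)
    fs = compute_substructures(food_smiles)
    trace: ForwardTrace = model.forward_single(
        ds, build_molecular_graph(drug_smiles), fs, build_molecular_graph(food_smiles)
    )
    rep_d = _report("drug", drug_smiles, ds, trace.drug_attention, trace.drug_dci, k)
    rep_f = _report("food", food_smiles, fs, trace.food_attention, trace.food_dci, k)
    return rep_d, rep_f, trace.y_hat


def write_report(report: ExplanationReport, out_dir, prefix: str) -> None:
    """Write per-head attention matrices (TSV, isoenzyme rows; bit-index then
    pseudo column headers) and the DCI score matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = report.attention.n
    header = [str(b) for b in report.substructures.bits] + [
        f"pseudo_{i}" for i in range(report.attention.n_pseudo)
    ]
    for head in range(report.attention.weights.shape[0]):
        path = out / f"{prefix}_head{head}_attention.tsv"
        with open(path, "w") as fh:
            fh.write("isoenzyme\t" + "\t".join(header) + "\n")
            for j, iso in enumerate(ISOENZYMES):
                row = report.attention.weights[head, j]
                fh.write(iso + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    with open(out / f"{prefix}_dci_scores.tsv", "w") as fh:
        fh.write("interaction_type\t" + "\t".join(ISOENZYMES) + "\n")
        for t, typ in enumerate(INTERACTION_TYPES):
            fh.write(typ + "\t" + "\t".join(f"{v:.6g}" for v in report.dci.scores[t]) + "\n")
    with open(out / f"{prefix}_top_substructures.tsv", "w") as fh:
        fh.write("head\tisoenzyme\trank\tbit\tweight\tatoms\n")
        for (head, iso), entries in sorted(report.top_substructures.items()):
            for rank, (bit, w, atoms) in enumerate(entries, 1):
                fh.write(
                    f"{head}\t{iso}\t{rank}\t{bit}\t{w:.6g}\t{','.join(map(str, sorted(atoms)))}\n"
                )


def render_highlights(report: ExplanationReport, out_dir, prefix: str, head: int = 0) -> None:
    """Optional convenience: draw the molecule with the top-attended atoms
    highlighted (one PNG per isoenzyme).  The TSV matrices are the contract;
    images are best-effort."""
    from rdkit import Chem
    from rdkit.Chem.Draw import rdMolDraw2D

    mol = Chem.MolFromSmiles(report.smiles)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for iso in ISOENZYMES:
        atoms = sorted({a for _, _, ats in report.top_substructures[(head, iso)] for a in ats})
        drawer = rdMolDraw2D.MolDraw2DCairo(400, 300)
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol, highlightAtoms=atoms)
        drawer.FinishDrawing()
        with open(out / f"{prefix}_{iso}_head{head}.png", "wb") as fh:
            fh.write(drawer.GetDrawingText())
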
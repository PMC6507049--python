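"""Comparative models for homologous sequences and the per-orthologue survey.

Homologue models are built by sidechain replacement on a template structure
from a pairwise row of a multiple sequence alignment: matched columns with a
different residue are mutated, columns where the target has a gap delete
the template residue, and columns where the template has a gap (an insertion
in the target) are flagged unmodelled — no loop building is attempted, so
patch and stability values stay comparable on the shared core.  Models whose
coverage falls below 0.8 are marked low-confidence.

The survey then runs the full pipeline per model (surface → potential →
patches → ratio; sites → titration → pH stability) and tabulates one row
per orthologue, with a ratio histogram alongside.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._constants import AA3_TO_1
from .mutagenesis import MutationSpec, mutate_sidechain
from .pipeline import RunConfig, profile_structure
from .structure_io import Structure
from .titration import ph_stability_for_structure

LOW_COVERAGE = 0.8
GAP = "-"


@dataclass(frozen=True)
class AlignmentRow:
    """A target sequence aligned against the template (equal lengths)."""

    name: str
    target: str
    template: str

    def __post_init__(self):
        if len(self.target) != len(self.template):
            raise ValueError(
                f"{self.name}: aligned rows differ in length "
                f"({len(self.target)} vs {len(self.template)})"
            )


@dataclass
class OrthologModel:
    name: str
    structure: Structure
    coverage: float
    unmodelled: list[int] = field(default_factory=list)  # alignment columns

    @property
    def low_confidence(self) -> bool:
        return self.coverage < LOW_COVERAGE


def read_alignment(fasta_text: str, template_name: str) -> list[AlignmentRow]:
    """Aligned-FASTA (gap '-') -> pairwise rows against the named template."""
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    by_name = {r.id: str(r.seq).upper() for r in records}
    if template_name not in by_name:
        raise KeyError(f"template row {template_name!r} not in alignment")
    tmpl = by_name[template_name]
    return [
        AlignmentRow(r.id, str(r.seq).upper(), tmpl)
        for r in records
        if r.id != template_name
    ]


def model_from_alignment(template: Structure, row: AlignmentRow) -> OrthologModel:
    """Sidechain-replacement comparative model for one alignment row."""
    chain = template.chains[0]
    residues = [
        (cid, seq, AA3_TO_1.get(name, "X"))
        for cid, seq, name, _ in template.residues()
        if cid == chain
    ]
    tmpl_ungapped = row.template.replace(GAP, "")
    struct_seq = "".join(aa for _, _, aa in residues)
    if tmpl_ungapped != struct_seq:
        for k, (a, b) in enumerate(zip(tmpl_ungapped, struct_seq)):
            if a != b:
                raise ValueError(
                    f"template alignment row disagrees with structure at "
                    f"ungapped position {k + 1}: alignment {a}, structure {b}"
                )
        raise ValueError(
            "template alignment row length differs from structure sequence"
        )

    mutations: list[MutationSpec] = []
    deletions: list[tuple[str, int]] = []
    unmodelled: list[int] = []
    ti = 0  # index into template residues
    for col, (t_aa, q_aa) in enumerate(zip(row.template, row.target)):
        if t_aa == GAP:
            if q_aa != GAP:
                unmodelled.append(col)
            continue
        cid, seq, struct_aa = residues[ti]
        ti += 1
        if q_aa == GAP:
            deletions.append((cid, seq))
        elif q_aa != t_aa:
            mutations.append(MutationSpec(cid, seq, struct_aa, q_aa))

    s = template
    for m in mutations:
        s = mutate_sidechain(s, m)
    if deletions:
        drop = set(deletions)
        s = Structure(
            [a.copy() for a in s.atoms if (a.chain_id, a.residue_seq) not in drop]
        )
    modelled = len(residues) - len(deletions)
    coverage = modelled / len(residues) if residues else 0.0
    # insertions penalise coverage too: they are target residues we cannot place
    if unmodelled:
        coverage = modelled / (len(residues) + len(unmodelled))
    return OrthologModel(row.name, s, coverage, unmodelled)


@dataclass
class SurveyTable:
    table: pd.DataFrame
    histogram: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)


def survey(
    models: list[OrthologModel],
    config: RunConfig,
    bin_width: float = 0.25,
) -> SurveyTable:
    """Per-orthologue posQmax ratio and pH-stability table.

    Failures of individual models are logged and skipped, never fatal.
    """
    if not models:
        raise ValueError("need at least one model")
    rows = []
    skipped = []
    for i, m in enumerate(models):
        try:
            out = profile_structure(m.structure, config)
            stab, _, _ = ph_stability_for_structure(
                out.structure,
                config.electrostatic_params,
                pH=config.ph,
                pH_grid=config.ph_grid,
                sweeps=config.sweeps,
                burn_in=config.burn_in,
                seed=config.seed,
            )
            rows.append(
                {
                    "name": m.name,
                    "ratio": out.profile.ratio,
                    "posQmax_A2": out.patches.posQmax,
                    "prediction": out.profile.prediction,
                    "pHstab_kJ_mol": stab.phstab,
                    "coverage": m.coverage,
                    "low_confidence": m.low_confidence,
                }
            )
        except Exception as exc:  # pragma: no cover - defensive path
            warnings.warn(f"model {m.name} skipped: {exc}")
            skipped.append((m.name, str(exc)))
    table = pd.DataFrame(rows)
    if len(table):
        lo = np.floor(table["ratio"].min() / bin_width) * bin_width
        hi = np.ceil(table["ratio"].max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 1e-9, bin_width)
        counts, edges = np.histogram(table["ratio"], bins=edges)
        hist = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
    else:
        hist = pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    return SurveyTable(table, hist, skipped)


def identity_order(rows: list[AlignmentRow]) -> list[int]:
    """UPGMA leaf order on pairwise percent-identity distance — used only to
    order survey rows for display."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    n = len(rows)
    if n < 3:
        return list(range(n))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i].target, rows[j].target
            pairs = [
                (x, y) for x, y in zip(a, b) if x != GAP and y != GAP
            ]
            ident = sum(x == y for x, y in pairs) / max(1, len(pairs))
            D[i, j] = D[j, i] = 1.0 - ident
    Z = average(squareform(D, checks=False))
    return list(leaves_list(Z))
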
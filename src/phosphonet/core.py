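"""Shared domain containers used across the pipeline.

Conventions:

* A phosphosite is identified by ``"PROTEIN_RES+POS"`` (e.g. ``"VCL_S275"``):
  protein id, one-letter residue (S, T or Y) and the 1-based position of that
  residue in the protein sequence.
* Intensity matrices are pandas DataFrames with unique row ids (site_id or
  protein_id) and sample ids as columns.  Missing measurements are NaN, never 0.
* Sequence windows are odd-length strings centred on the phosphoresidue and
  padded with ``"X"`` beyond the protein termini.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("phosphonet")

VALID_RESIDUES = frozenset("STY")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_CHAR = "X"

#: stage tags a relative-quantification matrix can carry
STAGES = ("centered", "protein_corrected", "log2")


def make_site_id(protein_id: str, residue: str, position: int) -> str:
    return f"{protein_id}_{residue}{position}"


@dataclass
class SampleDesign:
    """Maps samples to cohort groups with an explicit group ordering.

    ``group_order`` fixes the column order of group-profile matrices (the
    ordering in which expression patterns are read, e.g. HC, SLE_S, SLE_A, RA).
    """

    mapping: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_order:
            seen: list[str] = []
            for g in self.mapping.values():
                if g not in seen:
                    seen.append(g)
            self.group_order = seen
        extra = set(self.mapping.values()) - set(self.group_order)
        if extra:
            raise ValueError(f"groups missing from group_order: {sorted(extra)}")

    @property
    def samples(self) -> list[str]:
        return list(self.mapping)

    @property
    def groups(self) -> list[str]:
        return list(self.group_order)

    def samples_of(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise KeyError(f"unknown group label: {group!r}")
        return [s for s, g in self.mapping.items() if g == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.mapping), "group": list(self.mapping.values())}
        )


@dataclass
class RatioMatrix:
    """Relative quantification values (the site/protein ratio matrix R).

    ``stage`` records where in the pipeline the values sit: ``centered``
    (each row divided by its mean over present values, row means equal 1),
    ``protein_corrected`` (site ratios divided by parent-protein ratios) or
    ``log2``.  ``uncorrected`` lists site ids that passed through protein
    correction unchanged because their parent protein was not quantified.
    """

    values: pd.DataFrame
    stage: str
    uncorrected: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.values.index.is_unique:
            raise ValueError("ratio matrix row ids must be unique")


def validate_site_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a phosphosite table."""
    required = {"site_id", "protein_id", "residue", "position"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    dup = table["site_id"][table["site_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate site_id values: {sorted(set(dup))}")
    bad = table.loc[~table["residue"].isin(VALID_RESIDUES)]
    if len(bad):
        rows = ", ".join(f"{r.site_id} (residue {r.residue!r})" for r in bad.itertuples())
        raise ValueError(f"unknown residue code in rows: {rows}")
    if (table["position"] < 1).any():
        bad_ids = table.loc[table["position"] < 1, "site_id"].tolist()
        raise ValueError(f"positions must be 1-based positive: {bad_ids}")
    if "window" in table.columns:
        for r in table.itertuples():
            w = r.window
            if isinstance(w, str) and w:
                if len(w) % 2 != 1:
                    raise ValueError(f"window of {r.site_id} has even length {len(w)}")
                if w[len(w) // 2] != r.residue:
                    raise ValueError(
                        f"window centre of {r.site_id} is {w[len(w) // 2]!r}, "
                        f"expected {r.residue!r}"
                    )


def check_sites_against_sequences(table: pd.DataFrame, seqs: dict[str, str]) -> None:
    """Verify each site's residue letter against the protein FASTA."""
    for r in table.itertuples():
        seq = seqs.get(r.protein_id)
        if seq is None:
            continue
        pos = int(r.position)
        if pos > len(seq):
            raise ValueError(
                f"site {r.site_id}: position {pos} beyond sequence length {len(seq)}"
            )
        if seq[pos - 1] != r.residue:
            raise ValueError(
                f"site {r.site_id}: sequence has {seq[pos - 1]!r} at position {pos}, "
                f"table says {r.residue!r}"
            )
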
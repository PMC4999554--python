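"""Identity-threshold clade typing and phage-susceptibility prediction.

*E. faecalis* strains group into clades by the nucleotide identity of their
PIP variable regions: two strains belong to the same clade when their regions
share at least 95% identity (single-linkage, so clades are the connected
components of the ≥-threshold graph). Each clade carries a fixed
susceptibility pattern for the two sewage phages φVPE25 and φVFW, so typing a
new strain's variable region predicts which phage can kill it.

The packaged scheme encodes the published 19-strain roster and phenotype map
(clades 1 and 4 sensitive to both phages; clades 2 and 3 φVPE25-only; clade 5
φVFW-only). Its representative sequences are synthetic stand-ins generated
deterministically with the documented clade structure, since the public gene
sequences are not shipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .align import EXCLUDE_TERMINAL_GAPS, global_align, percent_identity
from .errors import InputError
from .records import NUCLEOTIDE
from .region import VariableRegion

PHAGE_VPE25 = "phiVPE25"
PHAGE_VFW = "phiVFW"
PHAGES = (PHAGE_VPE25, PHAGE_VFW)

SENSITIVE = "sensitive"
RESISTANT = "resistant"
UNKNOWN = "unknown"

NOVEL = "novel"

DEFAULT_THRESHOLD = 0.95


@dataclass(frozen=True)
class Clade:
    clade_id: str
    representative: Optional[VariableRegion]
    roster: tuple[str, ...]


@dataclass(frozen=True)
class CladeScheme:
    """Clade definitions plus the clade → phage-phenotype map."""

    clades: tuple[Clade, ...]
    susceptibility: dict  # clade_id -> {phage: phenotype}
    threshold: float = DEFAULT_THRESHOLD
    level: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for clade in self.clades:
            if not clade.roster:
                raise InputError(f"clade {clade.clade_id} has an empty roster")
            overlap = seen & set(clade.roster)
            if overlap:
                raise InputError(f"strains {sorted(overlap)} appear in more than one clade")
            seen |= set(clade.roster)
            phenos = self.susceptibility.get(clade.clade_id)
            if phenos is None or set(phenos) != set(PHAGES):
                raise InputError(
                    f"susceptibility map must cover both phages for clade {clade.clade_id}"
                )

    @property
    def clade_ids(self) -> tuple[str, ...]:
        return tuple(c.clade_id for c in self.clades)

    def clade(self, clade_id: str) -> Clade:
        for c in self.clades:
            if c.clade_id == clade_id:
                return c
        raise InputError(f"unknown clade id {clade_id!r}")

    def representatives(self) -> list[VariableRegion]:
        reps = [c.representative for c in self.clades]
        if any(r is None for r in reps):
            raise InputError("scheme has clades without representative sequences")
        return reps


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    clade_id: str  # a scheme clade id or "novel"
    best_identity: float
    margin: float  # identity gap to the second-best representative


@dataclass(frozen=True)
class SusceptibilityPrediction:
    query_id: str
    clade_id: str
    phenotypes: dict  # phage -> sensitive/resistant/unknown


def identity_matrix(
    regions: Sequence[VariableRegion],
    mode: str = EXCLUDE_TERMINAL_GAPS,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise global-alignment identities."""
    if len(regions) < 2:
        raise InputError("identity_matrix needs at least two regions")
    levels = {r.level for r in regions}
    if len(levels) != 1:
        raise InputError(f"regions mix levels {sorted(levels)}")
    ids = [r.source_id for r in regions]
    n = len(regions)
    mat = np.eye(n)
    recs = [r.as_record() for r in regions]
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(global_align(recs[i], recs[j]), mode)
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_clades(matrix: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> list[list[str]]:
    """Single-linkage partition at the identity threshold.

    Clades are the connected components of the graph whose edges join pairs
    with identity ≥ threshold, numbered by descending size and then by the
    input order of their first member.
    """
    adj = (matrix.values >= threshold).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    first_member: dict[int, int] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(matrix.index[idx])
        first_member.setdefault(lab, idx)
    order = sorted(groups, key=lambda lab: (-len(groups[lab]), first_member[lab]))
    return [groups[lab] for lab in order]


def medoid_index(matrix: pd.DataFrame, members: Sequence[str]) -> str:
    """Member with the highest mean identity to its clade-mates (first on ties)."""
    if len(members) == 1:
        return members[0]
    sub = matrix.loc[list(members), list(members)].values
    means = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
    return list(members)[int(np.argmax(means))]


def assign_clade(query: VariableRegion, scheme: CladeScheme) -> CladeAssignment:
    """Best-representative assignment at the scheme's threshold.

    An exact tie between the two best representatives is ambiguous and
    reports ``novel`` with a warning.
    """
    if query.level != scheme.level:
        raise InputError(f"query level {query.level!r} does not match scheme level")
    scheme.representatives()  # validates that every clade has one
    qrec = query.as_record()
    scored = []
    for clade in scheme.clades:
        ident = percent_identity(global_align(qrec, clade.representative.as_record()))
        scored.append((ident, clade.clade_id))
    scored.sort(key=lambda t: -t[0])
    best, best_clade = scored[0]
    second = scored[1][0] if len(scored) > 1 else 0.0
    margin = best - second
    if best < scheme.threshold:
        return CladeAssignment(query.source_id, NOVEL, best, margin)
    if len(scored) > 1 and second == best:
        warnings.warn(
            f"query {query.source_id!r} ties between clades "
            f"{best_clade} and {scored[1][1]}; reporting novel"
        )
        return CladeAssignment(query.source_id, NOVEL, best, 0.0)
    return CladeAssignment(query.source_id, best_clade, best, margin)


def predict_susceptibility(
    assignment: CladeAssignment, scheme: CladeScheme
) -> SusceptibilityPrediction:
    """Phenotype lookup from the scheme's clade → susceptibility map."""
    if assignment.clade_id == NOVEL:
        return SusceptibilityPrediction(
            assignment.query_id, NOVEL, {p: UNKNOWN for p in PHAGES}
        )
    if assignment.clade_id not in scheme.susceptibility:
        raise InputError(f"unknown clade id {assignment.clade_id!r}")
    return SusceptibilityPrediction(
        assignment.query_id,
        assignment.clade_id,
        dict(scheme.susceptibility[assignment.clade_id]),
    )


def load_scheme_table() -> pd.DataFrame:
    """The packaged roster/phenotype table (clade, strain, φVPE25, φVFW)."""
    with resources.files("piptype.data").joinpath("clade_scheme.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def packaged_scheme(with_sequences: bool = True, threshold: float = DEFAULT_THRESHOLD) -> CladeScheme:
    """The published five-clade, 19-strain scheme.

    Representative variable regions are synthetic stand-ins (deterministic,
    clade-structured) generated by :mod:`piptype.simulate`; pass
    ``with_sequences=False`` for roster/phenotype work that needs no
    sequence data.
    """
    table = load_scheme_table()
    reps: dict[str, VariableRegion] = {}
    if with_sequences:
        from .simulate import packaged_representatives

        reps = packaged_representatives()
    clades = []
    susceptibility = {}
    for clade_id, group in table.groupby("clade", sort=True):
        clades.append(
            Clade(
                clade_id=str(clade_id),
                representative=reps.get(str(clade_id)),
                roster=tuple(group["strain"]),
            )
        )
        susceptibility[str(clade_id)] = {
            PHAGE_VPE25: group[PHAGE_VPE25].iloc[0],
            PHAGE_VFW: group[PHAGE_VFW].iloc[0],
        }
    return CladeScheme(tuple(clades), susceptibility, threshold=threshold, level=NUCLEOTIDE)
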
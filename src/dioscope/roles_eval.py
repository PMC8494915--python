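"""Lead/Accm residue extraction from DIO clusters, and reference evaluation.

Within a DIO cluster, a residue that forms pairs with at least 80% of the
other residues of the system is a *leading* (Lead) residue — it takes
part in nearly all of the cluster's distinctive pairwise fluctuation
patterns and is hypothesised to drive them.  A residue pairing with at
least 60% but under 80% of the others is an *accompanying* (Accm)
residue.  Roles are read at the shallowest tree cut past which deeper
cuts stop yielding new receptor Lead/Accm residues; the cluster holding
the bulk of remaining pairs at that cut (typically the near-zero apo
background) is excluded.  Detected sets can be scored against an
externally supplied reference residue list (optionally renumbered through
a homolog mapping table) by recall and precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import RegionMap, assign_region

__all__ = [
    "EvaluationResult",
    "partner_fractions",
    "classify_lead_accm",
    "roles_at_cut",
    "stopping_rule",
    "extract_roles",
    "aggregate_combinations",
    "evaluate_against_reference",
    "LEAD_THRESHOLD",
    "ACCM_THRESHOLD",
]

LEAD_THRESHOLD = 0.8
ACCM_THRESHOLD = 0.6


@dataclass
class EvaluationResult:
    n_detected: int
    n_reference: int
    n_overlap: int
    recall: float
    precision: float | None  # None when nothing was detected
    overlap: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_detected, self.n_reference):
            raise ValueError("overlap exceeds set sizes")


def partner_fractions(
    cluster_pairs: list[tuple[int, int]], universe: set[int]
) -> dict[int, float]:
    """Fraction of the other residues each residue pairs with in a cluster.

    ``fraction(r) = |distinct partners of r| / (|universe| − 1)``.
    """
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 residues")
    partners: dict[int, set[int]] = {}
    for i, j in cluster_pairs:
        if i not in universe or j not in universe:
            raise ValueError(f"pair ({i}, {j}) not contained in universe")
        partners.setdefault(i, set()).add(j)
        partners.setdefault(j, set()).add(i)
    denom = len(universe) - 1
    return {r: len(p) / denom for r, p in partners.items()}


def classify_lead_accm(
    fractions: dict[int, float],
    lead_threshold: float = LEAD_THRESHOLD,
    accm_threshold: float = ACCM_THRESHOLD,
) -> dict[int, str]:
    """Role per residue: fraction ≥ lead → Lead; accm ≤ fraction < lead → Accm."""
    if not (0.0 < accm_threshold < lead_threshold <= 1.0):
        raise ValueError("need 0 < accm_threshold < lead_threshold <= 1")
    roles = {}
    for r, f in fractions.items():
        if f >= lead_threshold:
            roles[r] = "Lead"
        elif f >= accm_threshold:
            roles[r] = "Accm"
    return roles


def roles_at_cut(
    labels: np.ndarray,
    leaves: list[tuple[tuple[int, int], str]],
    universe: set[int],
    k: int,
    receptor_residues: set[int] | None = None,
    lead_threshold: float = LEAD_THRESHOLD,
    accm_threshold: float = ACCM_THRESHOLD,
    exclude_remainder: bool = True,
    region_map: RegionMap | None = None,
    combination: str = "",
) -> pd.DataFrame:
    """RoleTable rows for one tree cut.

    The remainder cluster — the one holding the most leaves at this cut —
    is skipped when ``exclude_remainder`` is set.  When
    ``receptor_residues`` is given, only roles of those residues are
    reported (ligand residues participate in the pairing statistics but
    are not assigned roles).
    """
    labels = np.asarray(labels)
    cluster_ids, sizes = np.unique(labels, return_counts=True)
    skip = {int(cluster_ids[np.argmax(sizes)])} if exclude_remainder else set()

    rows = []
    for cid in cluster_ids:
        if int(cid) in skip:
            continue
        pairs = [leaves[i][0] for i in np.flatnonzero(labels == cid)]
        sources = {leaves[i][1] for i in np.flatnonzero(labels == cid)}
        fractions = partner_fractions(pairs, universe)
        roles = classify_lead_accm(fractions, lead_threshold, accm_threshold)
        for r, role in sorted(roles.items()):
            if receptor_residues is not None and r not in receptor_residues:
                continue
            rows.append(
                {
                    "residue": r,
                    "role": role,
                    "cluster": int(cid),
                    "k": k,
                    "combination": combination,
                    "partner_fraction": fractions[r],
                    "sources": ",".join(sorted(sources)),
                    "region": assign_region(r, region_map) if region_map else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "residue", "role", "cluster", "k", "combination",
            "partner_fraction", "sources", "region",
        ],
    )


def stopping_rule(role_sets_by_k: dict[int, set[int]]) -> tuple[int, bool]:
    """Choose the clustering depth after which no new residues appear.

    Given the receptor Lead∪Accm residue set at each consecutive cut k,
    returns the smallest k whose successor adds nothing beyond the union
    of all cuts up to k.  If deeper cuts keep adding residues through the
    last k, the last k is returned with ``exhausted=True``.
    """
    ks = sorted(role_sets_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"k values must be consecutive, got {ks}")
    seen: set[int] = set()
    for k in ks[:-1]:
        seen |= role_sets_by_k[k]
        if role_sets_by_k[k + 1] <= seen:
            return k, False
    return ks[-1], True


def extract_roles(
    dendrogram,
    universe: set[int],
    k_range: tuple[int, int] = (2, 9),
    receptor_residues: set[int] | None = None,
    lead_threshold: float = LEAD_THRESHOLD,
    accm_threshold: float = ACCM_THRESHOLD,
    region_map: RegionMap | None = None,
    combination: str = "",
) -> tuple[pd.DataFrame, int, bool, dict[int, pd.DataFrame]]:
    """Scan cuts, apply the stopping rule, and return roles at the chosen k.

    Returns ``(role_table, chosen_k, exhausted, tables_by_k)``.
    """
    from .dio_cluster import cut_tree

    k_min, k_max = k_range
    tables: dict[int, pd.DataFrame] = {}
    sets: dict[int, set[int]] = {}
    for k in range(k_min, k_max + 1):
        labels = cut_tree(dendrogram, k)
        t = roles_at_cut(
            labels,
            dendrogram.leaves,
            universe,
            k,
            receptor_residues=receptor_residues,
            lead_threshold=lead_threshold,
            accm_threshold=accm_threshold,
            region_map=region_map,
            combination=combination,
        )
        tables[k] = t
        sets[k] = set(t["residue"].tolist())
    chosen_k, exhausted = stopping_rule(sets)
    return tables[chosen_k], chosen_k, exhausted, tables


def aggregate_combinations(
    tables: dict[str, pd.DataFrame],
    region_map: RegionMap | None = None,
) -> pd.DataFrame:
    """Union of per-combination role tables with per-residue provenance.

    One row per residue: the set of combinations it appeared in, the roles
    it held (a residue may be Lead in one combination and Accm in
    another), the source pair types, and its region label.
    """
    if not tables:
        raise ValueError("need at least one combination table")
    per_residue: dict[int, dict] = {}
    for combo, table in tables.items():
        for row in table.itertuples(index=False):
            rec = per_residue.setdefault(
                row.residue, {"roles": set(), "combinations": set(), "sources": set()}
            )
            rec["roles"].add(row.role)
            rec["combinations"].add(combo)
            rec["sources"].update(s for s in str(row.sources).split(",") if s)
    rows = []
    for residue in sorted(per_residue):
        rec = per_residue[residue]
        rows.append(
            {
                "residue": residue,
                "roles": "/".join(sorted(rec["roles"])),
                "combinations": ",".join(sorted(rec["combinations"])),
                "sources": ",".join(sorted(rec["sources"])),
                "n_combinations": len(rec["combinations"]),
                "region": assign_region(residue, region_map) if region_map else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["residue", "roles", "combinations", "sources", "n_combinations", "region"],
    )


def evaluate_against_reference(
    detected: set[int],
    reference: set[int],
    mapping: dict[int, int] | None = None,
) -> EvaluationResult:
    """Recall and precision of a detected residue set against a reference.

    ``mapping`` renumbers reference residues (e.g. from a homolog) into
    the detected set's numbering; it must be injective on the reference.
    Precision is ``None`` (undefined) when nothing was detected.
    """
    detected = set(detected)
    reference = set(reference)
    if not reference:
        raise ValueError("reference set is empty")
    if mapping is not None:
        mapped = [mapping[r] for r in reference if r in mapping]
        if len(set(mapped)) != len(mapped):
            raise ValueError("mapping is not injective on the reference set")
        reference = set(mapped)
        if not reference:
            raise ValueError("mapping covers no reference residue")
    overlap = detected & reference
    return EvaluationResult(
        n_detected=len(detected),
        n_reference=len(reference),
        n_overlap=len(overlap),
        recall=len(overlap) / len(reference),
        precision=(len(overlap) / len(detected)) if detected else None,
        overlap=frozenset(overlap),
    )
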
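"""Candidate-gene cascade: shared-DEG categories, stage specificity,
cross-species orthology exclusion, and transcription-factor selection.

The cascade narrows the gene lists of five two-condition comparisons in the
heterophyllous tetraploid (*C. palustris*) down to a candidate set for
differential leaf development, then removes candidates whose behaviour is
mirrored in the non-heterophyllous diploid relative (*C. terrestris*).

Direction convention: every log2 fold-change is log2(treatment / submerged
control), so call "up" means higher expression out of water (aerial-like
conditions) and lower in the submerged control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

__all__ = [
    "OrthologyMap",
    "CandidateReport",
    "assign_shared_categories",
    "classify_stage_specificity",
    "apply_crossspecies_exclusion",
    "select_tf_candidates",
    "upset_counts",
    "run_cascade",
]

TREATMENT_COMPARISONS = ("aerial", "agno3", "aba", "uniconazole")
CORE_COMPARISONS = ("aerial", "agno3", "aba")  # the three that phenocopy aerial leaves


@dataclass
class OrthologyMap:
    """Diploid <-> tetraploid gene links with relation class.

    ``links`` has columns (ct_gene, cp_gene, relation) with relation in
    {one_to_one, one_to_multi}; every link counts as a comparable ortholog.
    A tetraploid (cp) gene appears in at most one link; tetraploid genes in
    ``orphans`` have no diploid counterpart.
    """

    links: pd.DataFrame
    orphans: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"ct_gene", "cp_gene", "relation"}
        if not required.issubset(self.links.columns):
            raise ValueError(f"orthology links need columns {sorted(required)}")
        bad = set(self.links["relation"]) - {"one_to_one", "one_to_multi"}
        if bad:
            raise ValueError(f"unknown relation classes: {sorted(bad)}")
        if self.links["cp_gene"].duplicated().any():
            dup = self.links.loc[self.links["cp_gene"].duplicated(), "cp_gene"].iloc[0]
            raise ValueError(f"tetraploid gene {dup!r} appears in more than one link")
        per_ct = self.links.groupby("ct_gene")["relation"].nunique()
        if (per_ct > 1).any():
            raise ValueError("a diploid gene's links must share one relation class")

    def ortholog_of(self, cp_gene: str) -> str | None:
        """Diploid comparable ortholog of a tetraploid gene, or None."""
        hits = self.links.loc[self.links["cp_gene"] == cp_gene, "ct_gene"]
        return None if hits.empty else hits.iloc[0]

    def cp_to_ct(self) -> pd.Series:
        return self.links.set_index("cp_gene")["ct_gene"]


@dataclass
class CandidateReport:
    """Per-gene audit trail of the cascade plus summary accounting."""

    table: pd.DataFrame  # per-gene: category, direction, stage, exclusion, flags
    upset: pd.DataFrame  # intersection counts over the five comparisons
    summary: dict

    def retained_genes(self) -> pd.Index:
        return self.table.index[self.table["retained"]]


def _check_same_universe(tables: dict) -> pd.Index:
    items = list(tables.items())
    universe = items[0][1].index
    for name, tab in items[1:]:
        if not universe.equals(tab.index) and set(universe) != set(tab.index):
            raise ValueError(f"comparison {name!r} has a different gene universe")
    return universe


def assign_shared_categories(deg_tables: dict) -> pd.DataFrame:
    """Shared-DEG category per gene from the four treated-vs-submerged tables.

    ``deg_tables`` maps the comparison names ``aerial``, ``agno3``, ``aba``,
    ``uniconazole`` to DEG tables (indexed by gene, with a ``call`` column).

    SHARED4: same-sign DEG in all four comparisons.  SHARED3_NOT_UNI:
    same-sign DEG in aerial/AgNO3/ABA but not a DEG at all under uniconazole
    (the comparison whose leaves stay submerged-like).  Everything else NONE.
    Returns a DataFrame with columns ``category`` and ``direction`` (the
    shared sign for categorized genes, else "none").
    """
    missing = [k for k in TREATMENT_COMPARISONS if k not in deg_tables]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    universe = _check_same_universe({k: deg_tables[k] for k in TREATMENT_COMPARISONS})

    calls = pd.DataFrame(
        {k: deg_tables[k]["call"].reindex(universe) for k in TREATMENT_COMPARISONS}
    )
    core = calls[list(CORE_COMPARISONS)]
    core_up = (core == "up").all(axis=1)
    core_down = (core == "down").all(axis=1)
    core_consistent = core_up | core_down
    uni = calls["uniconazole"]

    shared4 = core_consistent & (
        (core_up & (uni == "up")) | (core_down & (uni == "down"))
    )
    shared3 = core_consistent & (uni == "none")

    category = pd.Series("NONE", index=universe)
    category[shared4] = "SHARED4"
    category[shared3] = "SHARED3_NOT_UNI"
    direction = pd.Series("none", index=universe)
    direction[core_up & (category != "NONE")] = "up"
    direction[core_down & (category != "NONE")] = "down"
    return pd.DataFrame({"category": category, "direction": direction})


def classify_stage_specificity(candidates, mature_deg_table: pd.DataFrame) -> pd.Series:
    """Label each candidate ``dev_and_mature`` or ``dev_specific``.

    A candidate that is also a DEG (either sign) in the mature
    aerial-vs-submerged comparison is differential at both stages; the rest
    are specific to developing leaves.  The labels partition the candidates.
    """
    candidates = pd.Index(candidates)
    missing = candidates.difference(mature_deg_table.index)
    if len(missing):
        raise ValueError(f"candidates absent from mature table: {list(missing[:3])}")
    mature_call = mature_deg_table["call"].reindex(candidates)
    out = pd.Series("dev_specific", index=candidates, name="stage_specificity")
    out[mature_call != "none"] = "dev_and_mature"
    return out


def apply_crossspecies_exclusion(
    candidates: pd.DataFrame,
    ortho: OrthologyMap,
    ct_deg_table: pd.DataFrame,
    ct_tpm: pd.DataFrame,
    tpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Exclude candidates whose diploid orthologs explain away their signal.

    ``candidates`` is indexed by gene with a ``direction`` column (the
    candidate's own treated-vs-submerged sign).  Two ordered exclusion rules:

    1. ``ct_consistent_deg`` — the comparable ortholog is a *C. terrestris*
       DEG with the same direction; the response is not heterophylly-specific.
    2. ``downreg_ct_unexpressed`` — the candidate is downregulated in
       submerged primordia (direction "up" under the submerged-denominator
       convention) and its ortholog is unexpressed (TPM below the floor in
       every *C. terrestris* sample), so losing its expression evidently
       does not require heterophylly.

    Candidates without a comparable ortholog are always retained.
    Returns the candidate table with ``exclusion_reason`` and ``retained``.
    """
    cp_to_ct = ortho.cp_to_ct()
    reasons = pd.Series("none", index=candidates.index, name="exclusion_reason")
    for gene in candidates.index:
        ct_gene = cp_to_ct.get(gene)
        if ct_gene is None:
            continue
        if ct_gene not in ct_deg_table.index:
            raise ValueError(f"ortholog {ct_gene!r} missing from C. terrestris DEG table")
        if ct_gene not in ct_tpm.index:
            raise ValueError(f"ortholog {ct_gene!r} missing from C. terrestris TPM table")
        ct_call = ct_deg_table.loc[ct_gene, "call"]
        direction = candidates.loc[gene, "direction"]
        if ct_call != "none" and ct_call == direction:
            reasons[gene] = "ct_consistent_deg"
        elif direction == "up" and (ct_tpm.loc[ct_gene] < tpm_threshold).all():
            reasons[gene] = "downreg_ct_unexpressed"
    out = candidates.copy()
    out["has_ortholog"] = out.index.isin(cp_to_ct.index)
    out["exclusion_reason"] = reasons
    out["retained"] = reasons == "none"
    return out


def select_tf_candidates(retained: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Transcription-factor candidates among the retained genes.

    ``annotation`` is indexed by gene with boolean ``has_orf`` and ``is_tf``
    columns; a TF flag without a predicted coding region is ignored (a TF
    call requires an ORF).  Returns the selected subset with its direction,
    and the split into genes up in submerged leaves (direction "down") vs
    up in aerial-like conditions is available from that column.
    """
    if retained.empty:
        return retained.iloc[0:0].assign(has_orf=[], is_tf=[])
    missing = retained.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"annotation missing for retained genes: {list(missing[:3])}")
    ann = annotation.reindex(retained.index)
    selected = retained[ann["has_orf"].astype(bool) & ann["is_tf"].astype(bool)].copy()
    selected["has_orf"] = True
    selected["is_tf"] = True
    return selected


def upset_counts(deg_tables: dict, direction: str) -> pd.DataFrame:
    """Exclusive intersection counts of DEG sets across comparisons.

    For the given ``direction`` ("up" or "down"), each gene that is a DEG in
    at least one comparison is assigned to the exact subset of comparisons
    calling it; counts over all non-empty subsets therefore sum, per
    comparison, to that comparison's total DEG count in this direction.
    """
    names = list(deg_tables)
    universe = _check_same_universe(deg_tables)
    member = pd.DataFrame(
        {k: (deg_tables[k]["call"].reindex(universe) == direction) for k in names}
    )
    rows = []
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            in_subset = member[list(subset)].all(axis=1)
            out_subset = ~member[[k for k in names if k not in subset]].any(axis=1) \
                if len(subset) < len(names) else pd.Series(True, index=universe)
            count = int((in_subset & out_subset).sum())
            if count:
                rows.append({"comparisons": "+".join(subset), "direction": direction, "count": count})
    return pd.DataFrame(rows, columns=["comparisons", "direction", "count"])


def run_cascade(
    deg_tables: dict,
    mature_deg_table: pd.DataFrame,
    ortho: OrthologyMap,
    ct_deg_table: pd.DataFrame,
    ct_tpm: pd.DataFrame,
    annotation: pd.DataFrame,
    tpm_threshold: float = 1.0,
) -> CandidateReport:
    """Execute the full cascade and assemble the per-gene audit trail.

    Stages: shared-category assignment over the four primordium comparisons
    -> stage-specificity against the mature-leaf comparison -> cross-species
    orthology exclusion -> TF selection among retained genes with ORFs.
    """
    cats = assign_shared_categories(deg_tables)
    candidates = cats[cats["category"] != "NONE"]

    stage = classify_stage_specificity(candidates.index, mature_deg_table)
    excl = apply_crossspecies_exclusion(candidates, ortho, ct_deg_table, ct_tpm, tpm_threshold)

    table = cats.copy()
    table["stage_specificity"] = stage.reindex(table.index, fill_value="")
    table["has_ortholog"] = excl["has_ortholog"].reindex(table.index, fill_value=False)
    table["exclusion_reason"] = excl["exclusion_reason"].reindex(table.index, fill_value="none")
    table["retained"] = excl["retained"].reindex(table.index, fill_value=False)

    ann = annotation.reindex(table.index)
    table["has_orf"] = ann["has_orf"].eq(True)  # NaN (unannotated) -> False
    table["is_tf"] = table["has_orf"] & ann["is_tf"].eq(True)

    retained = excl[excl["retained"]]
    tf = select_tf_candidates(retained, annotation)
    table["tf_candidate"] = table.index.isin(tf.index)

    five = dict(deg_tables)
    five["mature"] = mature_deg_table
    upset = pd.concat(
        [upset_counts(five, "up"), upset_counts(five, "down")], ignore_index=True
    )

    summary = {
        "n_genes": int(len(table)),
        "n_shared4": int((table["category"] == "SHARED4").sum()),
        "n_shared3_not_uni": int((table["category"] == "SHARED3_NOT_UNI").sum()),
        "n_candidates": int(len(candidates)),
        "n_dev_specific": int((stage == "dev_specific").sum()),
        "n_dev_and_mature": int((stage == "dev_and_mature").sum()),
        "n_excluded_ct_consistent": int((excl["exclusion_reason"] == "ct_consistent_deg").sum()),
        "n_excluded_ct_unexpressed": int(
            (excl["exclusion_reason"] == "downreg_ct_unexpressed").sum()
        ),
        "n_retained": int(excl["retained"].sum()),
        "n_retained_no_ortholog": int((retained["has_ortholog"] == False).sum()),  # noqa: E712
        "n_retained_orf": int((table["retained"] & table["has_orf"]).sum()),
        "n_tf_candidates": int(len(tf)),
        "n_tf_up_in_submerged": int((tf["direction"] == "down").sum()),
    }
    return CandidateReport(table=table, upset=upset, summary=summary)
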
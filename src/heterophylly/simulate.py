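"""Synthetic inputs with the statistical structure the analysis assumes.

Emulates the study design of the heterophylly experiment: negative-binomial
gene counts for *C. palustris* leaf primordia under five conditions (aerial;
submerged control; submerged + AgNO3, uniconazole P, or ABA) plus mature
aerial/submerged leaves, *C. terrestris* primordia under two conditions
(three biological replicates everywhere), a tetraploid<->diploid orthology
map with one-to-one and one-to-two relations, planted candidate-gene
expression signatures, and synthetic cell contours (lobed "jigsaw" pavement
cells, round palisade cells, elongated cells).

All randomness flows from one explicit seed through a named NumPy
generator; fixed seed means bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ellipe
from shapely.geometry import Polygon

from .cascade import OrthologyMap, TREATMENT_COMPARISONS
from .de import CountMatrix, call_degs
from .morphometrics import CellContour

__all__ = [
    "ExperimentDesign",
    "PlantedProfile",
    "ContourSpec",
    "simulate_orthology",
    "simulate_counts",
    "generate_cell_population",
    "default_cp_design",
    "default_ct_design",
    "simulate_experiment",
    "SimulatedStudy",
    "planted_cascade_fixture",
    "CascadeFixture",
]

PRIMORDIUM_CONDITIONS = ("aerial", "submerged", "agno3", "uniconazole", "aba")
DEFAULT_DISPERSION = 0.05  # configuration, not a claim about the real libraries


# ---------------------------------------------------------------------------
# designs and profiles


@dataclass
class ExperimentDesign:
    """Which samples exist: species x (condition, stage) cells x replicates."""

    species: str
    cells: list  # list of (condition, stage) tuples
    replicates: int = 3
    n_genes: int = 2000
    length_range: tuple = (500, 3000)  # effective length in bases

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per design cell")
        if self.n_genes < 1:
            raise ValueError("gene count must be positive")
        if self.length_range[0] <= 0:
            raise ValueError("effective lengths must be positive")

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for condition, stage in self.cells:
            for rep in range(1, self.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{self.species}_{stage}_{condition}_r{rep}",
                        "species": self.species,
                        "condition": condition,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PlantedProfile:
    """One gene's planted expression signature.

    ``log2fc`` maps (condition, stage) to the planted log2 fold-change
    relative to the submerged control of that stage; absent cells default
    to 0.  ``category`` records the intended cascade truth label.
    """

    gene_id: str
    baseline: float
    dispersion: float = DEFAULT_DISPERSION
    log2fc: dict = field(default_factory=dict)
    category: str = "BACKGROUND"

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    def mean_for(self, condition: str, stage: str) -> float:
        return self.baseline * 2.0 ** self.log2fc.get((condition, stage), 0.0)


def default_cp_design(n_genes: int = 2000, replicates: int = 3) -> ExperimentDesign:
    """The tetraploid design: five primordium conditions plus mature leaves."""
    cells = [(c, "primordium") for c in PRIMORDIUM_CONDITIONS]
    cells += [("aerial", "mature"), ("submerged", "mature")]
    return ExperimentDesign("Cp", cells, replicates, n_genes)


def default_ct_design(n_genes: int = 800, replicates: int = 3) -> ExperimentDesign:
    """The diploid design: aerial vs submerged primordia only."""
    cells = [("aerial", "primordium"), ("submerged", "primordium")]
    return ExperimentDesign("Ct", cells, replicates, n_genes)


# ---------------------------------------------------------------------------
# orthology


def simulate_orthology(
    n_diploid_genes: int,
    duplication_prob: float = 0.52,
    orphan_prob: float = 0.1,
    seed: int = 0,
    ct_prefix: str = "Ct",
    cp_prefix: str = "Cp",
) -> OrthologyMap:
    """Diploid -> tetraploid ortholog map with one-to-one / one-to-two links.

    Each diploid gene links to two tetraploid co-orthologs with probability
    ``duplication_prob`` (the genome-duplication signature, capped at
    1-to-2), else to one.  A further ``orphan_prob`` fraction of the
    tetraploid gene set carries no link at all.
    """
    if n_diploid_genes < 0:
        raise ValueError("gene count must be non-negative")
    for name, p in (("duplication_prob", duplication_prob), ("orphan_prob", orphan_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if orphan_prob >= 1.0 and n_diploid_genes > 0:
        raise ValueError("orphan_prob must be < 1 when linked genes exist")

    rng = np.random.default_rng(seed)
    duplicated = rng.random(n_diploid_genes) < duplication_prob
    rows = []
    cp_counter = 0
    for i in range(n_diploid_genes):
        ct_gene = f"{ct_prefix}{i:05d}"
        relation = "one_to_multi" if duplicated[i] else "one_to_one"
        for _ in range(2 if duplicated[i] else 1):
            rows.append({"ct_gene": ct_gene, "cp_gene": f"{cp_prefix}{cp_counter:05d}", "relation": relation})
            cp_counter += 1
    n_linked = cp_counter
    n_orphans = int(round(n_linked * orphan_prob / (1.0 - orphan_prob))) if n_linked else 0
    orphans = [f"{cp_prefix}{cp_counter + i:05d}" for i in range(n_orphans)]
    links = pd.DataFrame(rows, columns=["ct_gene", "cp_gene", "relation"])
    return OrthologyMap(links=links, orphans=orphans)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    design: ExperimentDesign,
    profiles: list,
    seed: int = 0,
    depth_factors: dict | None = None,
) -> CountMatrix:
    """Negative-binomial counts for every profile under the given design.

    Per sample, counts are NB with mean ``baseline * 2**log2fc * depth``
    and variance ``mu + phi * mu**2``; ``phi = 0`` degenerates to Poisson.
    ``depth_factors`` maps sample_id to a multiplicative library-depth
    factor (default 1 for all).
    """
    if len(profiles) != design.n_genes:
        raise ValueError("every gene needs exactly one profile")
    rng = np.random.default_rng(seed)
    meta = design.sample_table()
    samples = meta["sample_id"].tolist()
    depth = np.array([1.0 if depth_factors is None else depth_factors.get(s, 1.0) for s in samples])

    lo, hi = design.length_range
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=design.n_genes).astype(float),
        index=[p.gene_id for p in profiles],
        name="effective_length",
    )

    counts = np.empty((design.n_genes, len(samples)), dtype=np.int64)
    cond_stage = list(zip(meta["condition"], meta["stage"]))
    for gi, prof in enumerate(profiles):
        mu = np.array([prof.mean_for(c, s) for c, s in cond_stage]) * depth
        if prof.dispersion == 0.0:
            counts[gi] = rng.poisson(mu)
        else:
            r = 1.0 / prof.dispersion
            counts[gi] = rng.negative_binomial(r, r / (r + mu))
    frame = pd.DataFrame(counts, index=lengths.index, columns=samples)
    return CountMatrix(frame, lengths, meta)


# ---------------------------------------------------------------------------
# contours


@dataclass
class ContourSpec:
    """Parametric cell-shape family for contour generation.

    ``lobed`` uses r(theta) = size * (1 + amplitude * sin(k * theta)), the
    jigsaw-pavement-cell caricature; ``ellipse``/``rectangle`` model
    elongated cells via ``aspect`` >= 1; ``circle`` models round palisade
    cells.
    """

    shape: str  # circle | ellipse | lobed | rectangle
    size: float = 1.0
    aspect: float = 1.0
    lobe_amplitude: float = 0.0
    lobe_count: int = 0
    rotation: float = 0.0
    n_vertices: int = 128

    def __post_init__(self) -> None:
        if self.shape not in {"circle", "ellipse", "lobed", "rectangle"}:
            raise ValueError(f"unknown shape class {self.shape!r}")
        if self.size <= 0 or self.aspect < 1:
            raise ValueError("size must be positive and aspect >= 1")
        if not 0.0 <= self.lobe_amplitude < 0.5:
            raise ValueError("lobe amplitude must lie in [0, 0.5)")
        if self.n_vertices < 16:
            raise ValueError("need at least 16 vertices")

    def base_vertices(self) -> np.ndarray:
        n = self.n_vertices
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        if self.shape == "circle":
            xy = self.size * np.column_stack([np.cos(theta), np.sin(theta)])
        elif self.shape == "lobed":
            r = self.size * (1.0 + self.lobe_amplitude * np.sin(self.lobe_count * theta))
            xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        elif self.shape == "ellipse":
            a, b = self.size * self.aspect, self.size
            xy = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        else:  # rectangle: walk the boundary at constant arc length
            length, width = self.size * self.aspect, self.size
            half = np.array([length / 2.0, width / 2.0])
            perim = 2.0 * (length + width)
            s = np.linspace(0.0, perim, n, endpoint=False)
            xy = np.empty((n, 2))
            for i, si in enumerate(s):
                if si < length:
                    xy[i] = (-half[0] + si, -half[1])
                elif si < length + width:
                    xy[i] = (half[0], -half[1] + (si - length))
                elif si < 2 * length + width:
                    xy[i] = (half[0] - (si - length - width), half[1])
                else:
                    xy[i] = (-half[0], half[1] - (si - 2 * length - width))
        c, s_ = np.cos(self.rotation), np.sin(self.rotation)
        return xy @ np.array([[c, s_], [-s_, c]])

    def analytic_descriptors(self) -> dict | None:
        """Closed-form descriptors of the noiseless shape, for oracle use.

        Available for circle, ellipse and rectangle; the lobed family has no
        convenient closed-form hull, so None is returned for it.
        """
        if self.shape == "circle":
            r = self.size
            return {
                "area": np.pi * r * r,
                "perimeter": 2.0 * np.pi * r,
                "circularity": 1.0,
                "solidity": 1.0,
                "aspect_ratio": 1.0,
                "length": 2.0 * r,
                "width": 2.0 * r,
            }
        if self.shape == "ellipse":
            a, b = self.size * self.aspect, self.size
            perim = 4.0 * a * ellipe(1.0 - (b / a) ** 2)
            area = np.pi * a * b
            return {
                "area": area,
                "perimeter": perim,
                "circularity": min(1.0, 4.0 * np.pi * area / perim**2),
                "solidity": 1.0,
                "aspect_ratio": self.aspect,
                "length": 2.0 * a,
                "width": 2.0 * b,
            }
        if self.shape == "rectangle":
            length, width = self.size * self.aspect, self.size
            area, perim = length * width, 2.0 * (length + width)
            return {
                "area": area,
                "perimeter": perim,
                "circularity": min(1.0, 4.0 * np.pi * area / perim**2),
                "solidity": 1.0,
                "aspect_ratio": self.aspect,
                "length": length,
                "width": width,
            }
        return None


def generate_cell_population(
    spec: ContourSpec,
    n: int,
    jitter: float = 0.0,
    seed: int = 0,
    group: str = "",
) -> tuple[list, dict | None]:
    """n simple closed polygons drawn around the spec's base shape.

    ``jitter`` perturbs each vertex with Gaussian noise of standard
    deviation ``jitter * size`` and scales each cell by a lognormal factor
    of the same sigma.  Returns the contours together with the analytic
    descriptors of the noiseless shape (None for the lobed class).
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    base = spec.base_vertices()
    theta = np.arctan2(base[:, 1], base[:, 0])
    harmonics = np.arange(1, 7)
    contours = []
    for i in range(n):
        for _attempt in range(20):
            if jitter:
                # smooth low-frequency radial noise keeps the contour
                # star-shaped (hence simple) at any vertex density
                a = rng.normal(0.0, jitter / harmonics)
                b = rng.normal(0.0, jitter / harmonics)
                field = (a @ np.cos(np.outer(harmonics, theta))
                         + b @ np.sin(np.outer(harmonics, theta)))
                scale = float(np.exp(rng.normal(0.0, jitter)))
                verts = base * (scale * np.exp(field))[:, None]
            else:
                verts = base
            if Polygon(verts).is_valid:
                break
        else:
            raise RuntimeError("could not generate a simple polygon; reduce jitter")
        contours.append(
            CellContour(verts, cell_id=f"{group or spec.shape}_{i:03d}", group=group or spec.shape)
        )
    return contours, spec.analytic_descriptors()


# ---------------------------------------------------------------------------
# full simulated study (counts + orthology + annotation + truth)


@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, plus the planted ground truth."""

    cp_counts: CountMatrix
    ct_counts: CountMatrix
    orthology: OrthologyMap
    annotation: pd.DataFrame  # cp genes: has_orf, is_tf, go_terms
    truth: pd.DataFrame  # cp genes: category, direction, mature_deg
    seed: int


def _planted_lfc(direction: str, magnitude: float, comparisons, mature: bool) -> dict:
    sign = 1.0 if direction == "up" else -1.0
    # planted signatures are defined relative to the submerged control, so a
    # gene "up" in aerial-like conditions carries +lfc in the *treated* cells
    lfc = {(c, "primordium"): sign * magnitude for c in comparisons}
    lfc[("submerged", "primordium")] = 0.0
    if mature:
        lfc[("aerial", "mature")] = sign * magnitude
    return lfc


def simulate_experiment(
    n_genes: int = 2000,
    n_ct_genes: int = 800,
    seed: int = 0,
    effect_lfc: float = 2.0,
    planted_baseline: float = 100.0,
    dispersion: float = DEFAULT_DISPERSION,
    n_shared4: int = 30,
    n_shared3: int = 20,
    n_ct_consistent: int = 10,
    n_ct_unexpressed: int = 10,
    mature_fraction: float = 0.5,
) -> SimulatedStudy:
    """Simulate the full two-species study with planted cascade categories.

    Planted genes receive |log2FC| = ``effect_lfc`` at baseline mean
    ``planted_baseline``; background genes are null with lognormal
    baselines.  CT_CONSISTENT genes carry a same-direction effect on their
    diploid ortholog; CT_UNEXPRESSED genes are up in aerial-like conditions
    while their ortholog is essentially silent.  ``mature_fraction`` of the
    planted candidates is also differential in mature leaves.
    """
    rng = np.random.default_rng(seed)
    ortho = simulate_orthology(
        n_ct_genes, duplication_prob=0.4, orphan_prob=0.15, seed=int(rng.integers(2**31))
    )
    linked_cp = ortho.links["cp_gene"].tolist()
    n_linked = len(linked_cp)
    n_cp_named = n_linked + len(ortho.orphans)
    if n_genes < n_cp_named:
        raise ValueError(f"n_genes must cover the orthology map ({n_cp_named} tetraploid genes)")
    cp_genes = ortho.links["cp_gene"].tolist() + list(ortho.orphans)
    cp_genes += [f"Cp{n_cp_named + i:05d}" for i in range(n_genes - n_cp_named)]
    unlinked_cp = cp_genes[n_linked:]

    n_planted = n_shared4 + n_shared3 + n_ct_consistent + n_ct_unexpressed
    # exclusion categories need linked genes with *distinct* diploid
    # orthologs, so draw them from one-to-one links; plain candidates stay
    # unlinked so their recovery does not depend on the orthology draw
    one_to_one_cp = ortho.links.loc[ortho.links["relation"] == "one_to_one", "cp_gene"].tolist()
    planted_linked = one_to_one_cp[: n_ct_consistent + n_ct_unexpressed]
    planted_unlinked = unlinked_cp[: n_shared4 + n_shared3]
    if len(planted_linked) < n_ct_consistent + n_ct_unexpressed or len(
        planted_unlinked
    ) < n_shared4 + n_shared3:
        raise ValueError("not enough genes to host the planted categories")

    truth = pd.DataFrame(
        {"category": "BACKGROUND", "direction": "none", "mature_deg": False},
        index=pd.Index(cp_genes, name="gene_id"),
    )
    profiles = {}
    assignments = (
        [("SHARED4", g) for g in planted_unlinked[:n_shared4]]
        + [("SHARED3_NOT_UNI", g) for g in planted_unlinked[n_shared4:]]
        + [("CT_CONSISTENT", g) for g in planted_linked[:n_ct_consistent]]
        + [("CT_UNEXPRESSED", g) for g in planted_linked[n_ct_consistent:]]
    )
    ct_effects = {}  # ct gene -> direction
    ct_silent = set()
    for category, gene in assignments:
        if category == "CT_UNEXPRESSED":
            direction = "up"  # downregulated in submerged primordia
        else:
            direction = "up" if rng.random() < 0.5 else "down"
        comps = TREATMENT_COMPARISONS if category != "SHARED3_NOT_UNI" else ("aerial", "agno3", "aba")
        mature = bool(rng.random() < mature_fraction)
        profiles[gene] = PlantedProfile(
            gene, planted_baseline, dispersion,
            _planted_lfc(direction, effect_lfc, comps, mature), category,
        )
        truth.loc[gene, ["category", "direction", "mature_deg"]] = [category, direction, mature]
        ct_gene = ortho.cp_to_ct().get(gene)
        if category == "CT_CONSISTENT":
            ct_effects[ct_gene] = direction
        elif category == "CT_UNEXPRESSED":
            ct_silent.add(ct_gene)

    baselines = np.exp(rng.normal(np.log(80.0), 1.0, size=n_genes))
    for gene, base in zip(cp_genes, baselines):
        if gene not in profiles:
            profiles[gene] = PlantedProfile(gene, float(base), dispersion)
    cp_counts = simulate_counts(
        default_cp_design(n_genes), [profiles[g] for g in cp_genes], seed=int(rng.integers(2**31))
    )

    ct_genes = sorted(set(ortho.links["ct_gene"]))
    ct_genes += [f"Ct{len(ct_genes) + i:05d}" for i in range(n_ct_genes - len(ct_genes))]
    ct_baselines = np.exp(rng.normal(np.log(80.0), 1.0, size=len(ct_genes)))
    ct_profiles = []
    for gene, base in zip(ct_genes, ct_baselines):
        if gene in ct_silent:
            # essentially zero counts: an unexpressed gene yields at most
            # stray reads, keeping its TPM under the floor in every sample
            ct_profiles.append(PlantedProfile(gene, 0.005, dispersion, {}, "CT_SILENT"))
        elif gene in ct_effects:
            lfc = {("aerial", "primordium"): (2.0 if ct_effects[gene] == "up" else -2.0) * effect_lfc / 2.0}
            ct_profiles.append(PlantedProfile(gene, planted_baseline, dispersion, lfc, "CT_DEG"))
        else:
            ct_profiles.append(PlantedProfile(gene, float(base), dispersion))
    ct_counts = simulate_counts(
        default_ct_design(len(ct_genes)), ct_profiles, seed=int(rng.integers(2**31))
    )

    is_candidate = truth["category"].isin(["SHARED4", "SHARED3_NOT_UNI", "CT_CONSISTENT", "CT_UNEXPRESSED"])
    has_orf = pd.Series(rng.random(n_genes) < 0.8, index=truth.index)
    is_tf = has_orf & pd.Series(rng.random(n_genes) < 0.1, index=truth.index)
    # background GO vocabulary plus one term over-represented in candidates,
    # so enrichment has signal to find
    terms = [f"GO:{i:07d}" for i in range(1, 31)]
    go = []
    for gene in truth.index:
        mine = [t for t in terms[1:] if rng.random() < 0.05]
        if is_candidate[gene] and rng.random() < 0.5:
            mine.append(terms[0])
        elif rng.random() < 0.02:
            mine.append(terms[0])
        go.append(";".join(sorted(mine)))
    annotation = pd.DataFrame(
        {"has_orf": has_orf, "is_tf": is_tf, "go_terms": go}, index=truth.index
    )
    truth["is_candidate_truth"] = is_candidate
    return SimulatedStudy(cp_counts, ct_counts, ortho, annotation, truth, seed)


# ---------------------------------------------------------------------------
# worked-example fixture: planted DEG tables realizing the printed arithmetic


@dataclass
class CascadeFixture:
    """Planted DEG-table fixture with known per-gene cascade truth."""

    deg_tables: dict  # aerial/agno3/aba/uniconazole -> DEG table (cp genes)
    mature_deg_table: pd.DataFrame
    orthology: OrthologyMap
    ct_deg_table: pd.DataFrame
    ct_tpm: pd.DataFrame
    annotation: pd.DataFrame
    truth: dict  # expected category/exclusion/stage/TF totals


def _deg_row(gene: str, comparison: str, state: str) -> dict:
    # planted (log2fc, q) pairs that the strict decision rule maps to the
    # intended call; calls themselves are derived via call_degs downstream
    lfc, q = {"up": (2.5, 0.001), "down": (-2.5, 0.001), "none": (0.2, 0.6)}[state]
    return {"gene_id": gene, "comparison": comparison, "log2fc": lfc, "pvalue": q / 2, "qvalue": q}


def _deg_table(states: dict, comparison: str) -> pd.DataFrame:
    rows = [_deg_row(g, comparison, s) for g, s in states.items()]
    table = pd.DataFrame(rows).set_index("gene_id", drop=False)
    table.index.name = None
    return call_degs(table, 0.05, 1.0)


def planted_cascade_fixture(
    seed: int = 0,
    n_shared4: int = 200,
    n_shared3: int = 87,
    n_excl_ct_deg: int = 22,
    n_excl_unexpressed: int = 15,
    n_dev_and_mature: int = 134,
    n_retained_no_ortholog: int = 145,
    n_retained_orf: int = 208,
    n_tf: int = 19,
    n_tf_up_in_submerged: int = 5,
    n_background: int = 400,
) -> CascadeFixture:
    """Gene-level DEG fixture realizing the published category arithmetic.

    Plants direction-signed DEG patterns for the two shared categories, the
    two orthology exclusion classes, the mature-stage partition and the
    ORF/TF annotation at the requested sizes, plus background genes with
    partial or sign-inconsistent patterns.  The defaults are the category
    sizes of the real analysis; the fixture exercises the cascade's set
    arithmetic, not its statistics.
    """
    n_candidates = n_shared4 + n_shared3
    n_excluded = n_excl_ct_deg + n_excl_unexpressed
    n_retained = n_candidates - n_excluded
    if n_retained < n_retained_no_ortholog:
        raise ValueError("more ortholog-free retained genes than retained genes")
    if n_retained_orf > n_retained or n_tf > n_retained_orf:
        raise ValueError("annotation sizes exceed the retained set")
    rng = np.random.default_rng(seed)

    genes = [f"Cp{i:05d}" for i in range(n_candidates + n_background)]
    rng.shuffle(genes)
    candidates = genes[:n_candidates]
    background = genes[n_candidates:]
    shared4 = candidates[:n_shared4]
    shared3 = candidates[n_shared4:]

    # order the candidate list so that slices give the planted subsets:
    # excluded-by-Ct-DEG, excluded-unexpressed, retained (145 of which get no
    # ortholog); TF genes are drawn from the retained slice
    excl_ct = candidates[:n_excl_ct_deg]
    excl_unexpr = candidates[n_excl_ct_deg:n_excluded]
    retained = candidates[n_excluded:]
    retained_with_ortholog = retained[: n_retained - n_retained_no_ortholog]

    # directions: the unexpressed exclusion class must be "up" (downregulated
    # in submerged); TF genes need the printed up-in-submerged split; the
    # rest alternate to populate both Fig-4 panels
    direction = {}
    for g in excl_unexpr:
        direction[g] = "up"
    tf_genes = retained[:n_tf]
    for i, g in enumerate(tf_genes):
        direction[g] = "down" if i < n_tf_up_in_submerged else "up"
    for g in candidates:
        if g not in direction:
            direction[g] = "up" if rng.random() < 0.55 else "down"

    # four treated-vs-submerged comparisons
    states = {c: {} for c in TREATMENT_COMPARISONS}
    for g in shared4:
        for c in TREATMENT_COMPARISONS:
            states[c][g] = direction[g]
    for g in shared3:
        for c in ("aerial", "agno3", "aba"):
            states[c][g] = direction[g]
        states["uniconazole"][g] = "none"
    # background patterns: partial membership, sign flips, uni-only, null
    for i, g in enumerate(background):
        kind = i % 4
        if kind == 0:  # DEG in aerial only
            for c in TREATMENT_COMPARISONS:
                states[c][g] = "up" if c == "aerial" else "none"
        elif kind == 1:  # sign flip inside the core trio
            states["aerial"][g] = "up"
            states["agno3"][g] = "down"
            states["aba"][g] = "up"
            states["uniconazole"][g] = "none"
        elif kind == 2:  # core-consistent but uniconazole flips sign
            for c in ("aerial", "agno3", "aba"):
                states[c][g] = "down"
            states["uniconazole"][g] = "up"
        else:  # null everywhere
            for c in TREATMENT_COMPARISONS:
                states[c][g] = "none"
    deg_tables = {c: _deg_table(states[c], c) for c in TREATMENT_COMPARISONS}

    # mature-leaf comparison: a planted subset of the candidates is
    # differential at both stages; some background genes are mature-only DEGs
    mature_members = set(candidates[:0])
    pool = list(candidates)
    rng.shuffle(pool)
    mature_members = set(pool[:n_dev_and_mature])
    mature_states = {
        g: (direction[g] if g in mature_members else "none") for g in candidates
    }
    for i, g in enumerate(background):
        mature_states[g] = "up" if i % 7 == 0 else "none"
    mature = _deg_table({g: mature_states[g] for g in genes}, "mature")

    # orthology: excluded genes all carry comparable orthologs; retained
    # genes beyond the ortholog-free quota carry orthologs whose behaviour
    # does not trigger either rule
    links = []
    ct_states = {}
    ct_expressed = {}
    ct_counter = 0

    def _link(cp_gene: str, relation: str = "one_to_one") -> str:
        nonlocal ct_counter
        ct_gene = f"Ct{ct_counter:05d}"
        ct_counter += 1
        links.append({"ct_gene": ct_gene, "cp_gene": cp_gene, "relation": relation})
        return ct_gene

    for g in excl_ct:
        ct_gene = _link(g)
        ct_states[ct_gene] = direction[g]  # same-direction Ct DEG
        ct_expressed[ct_gene] = True
    for g in excl_unexpr:
        ct_gene = _link(g)
        ct_states[ct_gene] = "none"
        ct_expressed[ct_gene] = False  # TPM below the floor everywhere
    for i, g in enumerate(retained_with_ortholog):
        ct_gene = _link(g)
        if i % 3 == 0:  # opposite-direction Ct DEG: not a consistent response
            ct_states[ct_gene] = "down" if direction[g] == "up" else "up"
        else:
            ct_states[ct_gene] = "none"
        ct_expressed[ct_gene] = True
    ortho = OrthologyMap(pd.DataFrame(links, columns=["ct_gene", "cp_gene", "relation"]))

    ct_deg = _deg_table(ct_states, "ct_aerial_vs_submerged")
    samples = [f"Ct_primordium_{c}_r{r}" for c in ("aerial", "submerged") for r in (1, 2, 3)]
    tpm_rows = {}
    for ct_gene in ct_states:
        if ct_expressed[ct_gene]:
            tpm_rows[ct_gene] = rng.uniform(5.0, 50.0, size=len(samples))
        else:
            tpm_rows[ct_gene] = rng.uniform(0.0, 0.4, size=len(samples))
    ct_tpm = pd.DataFrame.from_dict(tpm_rows, orient="index", columns=samples)

    # annotation: ORFs for the planted count among retained genes (and for a
    # slice of the rest); TF flags only on ORF-bearing genes
    has_orf = {g: False for g in genes}
    for g in retained[:n_retained_orf]:
        has_orf[g] = True
    for g in background[: len(background) // 2]:
        has_orf[g] = True
    is_tf = {g: g in set(tf_genes) for g in genes}
    for i, g in enumerate(background):
        if has_orf[g] and i % 11 == 0:
            is_tf[g] = True  # TF-flagged background genes must never surface
    annotation = pd.DataFrame(
        {
            "has_orf": pd.Series(has_orf),
            "is_tf": pd.Series(is_tf),
            "go_terms": "",
        }
    ).loc[genes]

    truth = {
        "n_candidates": n_candidates,
        "n_shared4": n_shared4,
        "n_shared3_not_uni": n_shared3,
        "n_excluded_ct_consistent": n_excl_ct_deg,
        "n_excluded_ct_unexpressed": n_excl_unexpressed,
        "n_retained": n_retained,
        "n_retained_no_ortholog": n_retained_no_ortholog,
        "n_dev_and_mature": n_dev_and_mature,
        "n_dev_specific": n_candidates - n_dev_and_mature,
        "n_retained_orf": n_retained_orf,
        "n_tf_candidates": n_tf,
        "n_tf_up_in_submerged": n_tf_up_in_submerged,
        "candidate_genes": set(candidates),
        "retained_genes": set(retained),
        "tf_genes": set(tf_genes),
    }
    return CascadeFixture(deg_tables, mature, ortho, ct_deg, ct_tpm, annotation, truth)
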
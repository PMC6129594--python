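"""Synthetic structural-connectome cohorts with known ground truth.

Real diffusion-imaging cohorts cannot ship with the package, so every
downstream stage is exercised on simulated subjects whose asymmetry,
group, nodal and clinical effects are injected explicitly and are
therefore recoverable.

The generator emulates the cohort structure of a typical case-control
laterality study: 49 patients (group ``BD``) and 61 controls (``NC``),
ages 21-50, both genders, 45 regions per hemisphere.  A mirror-
symmetric whole-brain template is built once per specification: each
intra-hemispheric block is a Watts-Strogatz ring lattice (rewiring
probability 0.1) at the requested edge density, so small-world
topology holds by construction; FA weights are Beta-distributed (the
default Beta(4, 6) concentrates around 0.4, typical of white-matter
tracts); homotopic inter-hemispheric edges are included so that the
inter-hemispheric elimination step has something to remove.

Per subject, FA weights are perturbed multiplicatively (hemisphere /
group / nodal multipliers) and additively (Gaussian noise), fiber
counts are drawn Poisson with mean proportional to template FA, and a
configurable fraction of empty node pairs receives spurious edges with
fiber number 1-3 — exactly the edges the FN > 3 filter must remove.
Mania scores (YMRS) are generated linearly from each patient's
realized regional asymmetry, so correlation analyses have a known
ground truth; depression scores (HAMD) are unlinked noise.

Reproducibility: one master seed; subject i uses the independent
stream ``default_rng([seed, i])`` and metadata uses
``default_rng([seed, n_subjects])``, so cohorts are bitwise
reproducible and subjects statistically independent.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .construction import (
    ParcellationScheme,
    SubjectConnectome,
    construct_subject_networks,
    default_parcellation,
)
from .metrics import nodal_efficiency_vector, shortest_paths, weight_to_length

__all__ = [
    "SyntheticSpec",
    "NodalEffect",
    "ClinicalLink",
    "generate_template",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "spec_parcellation",
]


class NodalEffect(NamedTuple):
    """Multiplier on all FA edges incident to one region, in one group."""

    region: str
    hemisphere: str  # 'L' or 'R'
    group: str  # 'BD' or 'NC'
    multiplier: float


class ClinicalLink(NamedTuple):
    """Linear map from a patient's regional asymmetry score to YMRS."""

    region: str
    metric: str  # only 'Enodal' is supported
    slope: float
    intercept: float
    noise_sd: float


#: Slope/intercept/noise chosen so the implied YMRS distribution matches a
#: mania-score mean of about 12 with SD 11, and so that — given the
#: patient-group SD of the linked region's asymmetry score under the
#: default world (about 0.9) — the population correlation between YMRS
#: and that score is roughly 0.24.
DEFAULT_CLINICAL_LINK = ClinicalLink(
    region="ROL", metric="Enodal", slope=2.9, intercept=11.9, noise_sd=10.7
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated world.

    The defaults encode the reference cohort: 49 patients and 61
    controls, 45 regions per hemisphere at edge density 0.30, modest
    rightward FA asymmetry in controls (5%) and none in patients, and
    mania scores linked to rolandic-operculum asymmetry.
    """

    n_patients: int = 49
    n_controls: int = 61
    n_regions_per_hemisphere: int = 45
    edge_density: float = 0.30
    fa_weight_params: tuple[float, float] = (4.0, 6.0)
    fn_mean_scale: float = 60.0
    noise_sd: float = 0.03
    delta_right_control: float = 0.05
    delta_right_patient: float = 0.0
    nodal_effects: tuple[NodalEffect, ...] = ()
    clinical_link: ClinicalLink | None = DEFAULT_CLINICAL_LINK
    spurious_edge_rate: float = 0.05
    rewiring_prob: float = 0.1
    age_range: tuple[int, int] = (21, 50)
    education_range: tuple[int, int] = (11, 19)
    prop_male: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_regions_per_hemisphere <= 2:
            raise ValueError("need more than 2 regions per hemisphere")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.spurious_edge_rate < 1:
            raise ValueError("spurious_edge_rate must lie in [0, 1)")
        for delta in (self.delta_right_control, self.delta_right_patient):
            if 1 + delta <= 0:
                raise ValueError("hemisphere multiplier 1 + delta must be positive")
        for eff in self.nodal_effects:
            if eff.multiplier <= 0:
                raise ValueError("nodal multipliers must be positive")

    def delta_right(self, group: str) -> float:
        return self.delta_right_patient if group == "BD" else self.delta_right_control


@functools.lru_cache(maxsize=8)
def _synthetic_parcellation(n: int) -> ParcellationScheme:
    return ParcellationScheme.synthetic(n)


def spec_parcellation(spec: SyntheticSpec) -> ParcellationScheme:
    """Parcellation matching the spec: the packaged AAL-90 scheme when
    45 regions per hemisphere are requested, a generic alternating
    scheme otherwise."""
    if spec.n_regions_per_hemisphere == 45:
        return default_parcellation()
    return _synthetic_parcellation(spec.n_regions_per_hemisphere)


def _ring_lattice_k(density: float, n: int) -> int:
    """Even neighbour count approximating the requested edge density."""
    k = int(round(density * (n - 1)))
    if k % 2:
        k += 1 if k < n - 1 else -1
    return max(2, min(k, n - 1 if (n - 1) % 2 == 0 else n - 2))


def generate_template(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror-symmetric whole-brain (FN, FA) template matrices.

    The left and right intra-hemispheric blocks are identical entry by
    entry before any asymmetry is injected; homotopic regions are also
    joined across hemispheres.  Node order follows the parcellation
    (alternating L/R).
    """
    parc = spec_parcellation(spec)
    n_h = spec.n_regions_per_hemisphere
    n = 2 * n_h
    rng = np.random.default_rng([spec.seed, 2**30])
    k = _ring_lattice_k(spec.edge_density, n_h)
    if spec.edge_density == 1.0 and k < n_h - 1:
        import warnings

        warnings.warn("density 1 not reachable with even ring-lattice degree",
                      stacklevel=2)
    g = nx.watts_strogatz_graph(
        n_h, k, spec.rewiring_prob, seed=int(rng.integers(2**31))
    )
    a, b = spec.fa_weight_params

    fa = np.zeros((n, n))
    idx_l = parc.indices("L")
    idx_r = parc.indices("R")
    for u, v in g.edges():
        w = float(rng.beta(a, b))
        for idx in (idx_l, idx_r):
            fa[idx[u], idx[v]] = w
            fa[idx[v], idx[u]] = w
    # homotopic inter-hemispheric edges, removed later by the split
    for u in range(n_h):
        w = float(rng.beta(a, b))
        fa[idx_l[u], idx_r[u]] = w
        fa[idx_r[u], idx_l[u]] = w

    fn = np.where(fa > 0, np.maximum(1, np.rint(spec.fn_mean_scale * fa)), 0)
    return fn.astype(int), fa


def generate_subject(
    template: tuple[np.ndarray, np.ndarray],
    group: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    subject_id: str = "sub",
) -> SubjectConnectome:
    """One subject's (FN, FA) connectome drawn around the template.

    FA on the template support is ``clip(template * multipliers +
    N(0, noise_sd), 0.01, 1)``; fiber counts are Poisson with mean
    ``fn_mean_scale * template_FA`` (an edge whose count draw is 0
    vanishes for that subject, keeping FA and FN supports identical);
    spurious low-count edges (FN in {1, 2, 3}) appear on empty pairs at
    ``spurious_edge_rate``.  Nodal multipliers act per endpoint: an
    edge between two affected regions is multiplied twice.
    """
    if group not in ("BD", "NC"):
        raise ValueError(f"group must be 'BD' or 'NC', got {group!r}")
    fn_t, fa_t = template
    parc = spec_parcellation(spec)
    n = fa_t.shape[0]

    mult = np.ones((n, n))
    idx_r = parc.indices("R")
    delta = spec.delta_right(group)
    if delta != 0:
        block = np.ix_(idx_r, idx_r)
        mult[block] *= 1.0 + delta
    for eff in spec.nodal_effects:
        if eff.group != group:
            continue
        sel = parc.table[
            (parc.table["abbrev"] == eff.region)
            & (parc.table["hemisphere"] == eff.hemisphere)
        ]
        if sel.empty:
            raise ValueError(f"nodal effect region {eff.region}/{eff.hemisphere} "
                             "not in parcellation")
        i = int(sel["index"].iloc[0])
        mult[i, :] *= eff.multiplier
        mult[:, i] *= eff.multiplier

    support = np.triu(fa_t > 0, 1)
    iu, ju = np.nonzero(support)
    fa = np.zeros((n, n))
    vals = fa_t[iu, ju] * mult[iu, ju]
    if spec.noise_sd > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.size)
    vals = np.clip(vals, 0.01, 1.0)
    fn_vals = rng.poisson(spec.fn_mean_scale * fa_t[iu, ju])
    vals[fn_vals == 0] = 0.0  # edge absent this subject

    fa[iu, ju] = vals
    fn = np.zeros((n, n), dtype=int)
    fn[iu, ju] = fn_vals

    if spec.spurious_edge_rate > 0:
        empty = np.triu(fa_t == 0, 1)
        ei, ej = np.nonzero(empty)
        hit = rng.random(ei.size) < spec.spurious_edge_rate
        ei, ej = ei[hit], ej[hit]
        fn[ei, ej] = rng.integers(1, 4, size=ei.size)
        fa[ei, ej] = rng.uniform(0.01, 0.2, size=ei.size)

    fa = fa + fa.T
    fn = fn + fn.T
    return SubjectConnectome(subject_id=subject_id, fn=fn, fa=fa)


def _realized_regional_as(
    connectome: SubjectConnectome, spec: SyntheticSpec, link: ClinicalLink
) -> float:
    """The subject's actual asymmetry score of the linked nodal metric."""
    if link.metric != "Enodal":
        raise NotImplementedError(
            f"clinical link supports the nodal-efficiency metric only, "
            f"got {link.metric!r}"
        )
    parc = spec_parcellation(spec)
    left, right = construct_subject_networks(connectome, parc)
    labels = left.node_labels
    if link.region not in labels:
        raise ValueError(f"clinical link region {link.region!r} not in parcellation")
    pos = labels.index(link.region)
    vals = {}
    for net in (left, right):
        d = shortest_paths(weight_to_length(net.adjacency))
        vals[net.hemisphere] = nodal_efficiency_vector(d)[pos]
    total = vals["R"] + vals["L"]
    if total == 0:
        return float("nan")
    return 100.0 * (vals["R"] - vals["L"]) / total


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, list[SubjectConnectome]]:
    """A full cohort: metadata table plus one connectome per subject.

    Deterministic given ``spec.seed``.  Patient YMRS scores are
    generated from each patient's realized regional asymmetry through
    the clinical link (plus Gaussian noise, clipped at 0); controls
    score 0 on both clinical scales, mirroring instruments administered
    to patients only.
    """
    template = generate_template(spec)
    groups = ["BD"] * spec.n_patients + ["NC"] * spec.n_controls
    n_total = len(groups)
    meta_rng = np.random.default_rng([spec.seed, n_total])

    rows = []
    connectomes = []
    counters = {"BD": 0, "NC": 0}
    for i, group in enumerate(groups):
        counters[group] += 1
        sid = f"sub-{group}{counters[group]:03d}"
        rng = np.random.default_rng([spec.seed, i])
        conn = generate_subject(template, group, spec, rng, subject_id=sid)
        connectomes.append(conn)

        age = int(meta_rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        education = int(
            meta_rng.integers(spec.education_range[0], spec.education_range[1] + 1)
        )
        gender = "M" if meta_rng.random() < spec.prop_male else "F"

        if group == "BD":
            if spec.clinical_link is not None:
                link = spec.clinical_link
                as_val = _realized_regional_as(conn, spec, link)
                base = link.intercept + link.slope * (0.0 if np.isnan(as_val) else as_val)
                ymrs = max(0.0, base + meta_rng.normal(0.0, link.noise_sd))
            else:
                ymrs = max(0.0, meta_rng.normal(11.9, 11.0))
            hamd = max(0.0, meta_rng.normal(12.0, 8.4))
        else:
            ymrs = 0.0
            hamd = 0.0

        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": age,
                "gender": gender,
                "education": education,
                "ymrs": round(float(ymrs), 4),
                "hamd": round(float(hamd), 4),
            }
        )

    cohort = pd.DataFrame(rows)
    return cohort, connectomes


# ---------------------------------------------------------------------------
# on-disk cohort layout: metadata.tsv, parcellation.tsv, SUBJ_fn.tsv/_fa.tsv

_METADATA_COLUMNS = ["subject_id", "group", "age", "gender", "education",
                     "ymrs", "hamd"]


def write_cohort(
    dir_path,
    cohort: pd.DataFrame,
    connectomes: Sequence[SubjectConnectome],
    parcellation: ParcellationScheme,
) -> None:
    """Write a cohort directory: metadata and per-subject matrices."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    cohort[_METADATA_COLUMNS].to_csv(d / "metadata.tsv", sep="\t", index=False)
    parcellation.to_tsv(d / "parcellation.tsv")
    for conn in connectomes:
        np.savetxt(d / f"{conn.subject_id}_fn.tsv", conn.fn, fmt="%d", delimiter="\t")
        np.savetxt(d / f"{conn.subject_id}_fa.tsv", conn.fa, fmt="%.10g",
                   delimiter="\t")


def read_cohort(
    dir_path,
) -> tuple[pd.DataFrame, list[SubjectConnectome], ParcellationScheme]:
    """Load a cohort directory written by :func:`write_cohort`.

    Raises with the offending file named when metadata, parcellation or
    a subject matrix is missing, and with the subject named on a
    dimension mismatch.
    """
    d = Path(dir_path)
    meta_path = d / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"cohort metadata table not found: {meta_path}")
    parc_path = d / "parcellation.tsv"
    if not parc_path.exists():
        raise FileNotFoundError(f"parcellation file not found: {parc_path}")
    cohort = pd.read_csv(meta_path, sep="\t")
    missing_cols = set(_METADATA_COLUMNS) - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"{meta_path} missing columns: {sorted(missing_cols)}")
    parcellation = ParcellationScheme.from_tsv(parc_path)
    n = parcellation.n_nodes

    connectomes = []
    for sid in cohort["subject_id"]:
        mats = {}
        for kind in ("fn", "fa"):
            path = d / f"{sid}_{kind}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"connectome file not found: {path}")
            m = np.loadtxt(path, delimiter="\t", ndmin=2)
            if m.shape != (n, n):
                raise ValueError(
                    f"subject {sid}: {kind.upper()} matrix has shape "
                    f"{m.shape}, expected ({n}, {n})"
                )
            mats[kind] = m
        connectomes.append(
            SubjectConnectome(
                subject_id=str(sid),
                fn=mats["fn"].astype(int),
                fa=mats["fa"],
            )
        )
    return cohort, connectomes, parcellation
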
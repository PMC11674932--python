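"""Synthetic multi-center cohort generator.

Emulates a 7-center MS/HC cohort (~700 subjects, ~70% patients) with the
statistical structure the downstream analysis assumes, so the whole
pipeline is testable without any restricted data. The generative model is
this package's own construction (no public cohort is attached to the
analysis it mirrors):

* each subject draws a latent conservation factor u ~ N(0,1); patients
  additionally draw a latent severity s ~ N(0,1) truncated to [-2, 2];
* the interhemispheric streamline share is
  p_inter = logistic(mu0 + a*u - disease_effect_inter*s*is_ms + eps);
* a fixed streamline budget is allocated by a single multinomial draw:
  the interhemispheric cortical block receives the p_inter share, each
  intrahemispheric block (1 - p_inter)/2, a small fraction goes to
  subcortical connections; spanning-tree edges are seeded with one
  streamline each so every hemisphere graph is connected by construction;
* the planted inter/intra coupling: an intrahemispheric strength latent v
  is drawn with in-sample correlation ``conservation_coupling`` to the
  (standardized) interhemispheric logit, and realized through intra fiber
  lengths (strong-intra subjects have shorter intra fibers, hence larger
  length-normalized intra weights, higher efficiency and lower SPL);
* fiber lengths are lognormal with interhemispheric (callosal-scale) mean
  length above the intrahemispheric mean;
* CC area tracks p_inter, WMF tracks p_inter, LVF/EDSS rise and SDMT falls
  with severity; age/sex are drawn per center from ranges loosely matching
  a multi-center MS cohort;
* per-center batch effects: multiplicative scales on the weight-matrix
  blocks (drawn separately for inter- and intrahemispheric edges, so even
  the scale-invariant commissural ratio carries a center signature) and
  scale-and-shift distortions on the volumetric scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome
from . import io as hio

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_cohort"]

_LOGIT_BASE = np.log(0.2 / 0.8)   # baseline interhemispheric share ~0.2
_CONS_SLOPE = 0.35                # a: effect of u on the interhemispheric logit
_INTRA_STRENGTH_SD = 0.25         # log-scale sd of the planted intra strength
_INTER_LENGTH_MM = 90.0           # mean interhemispheric (callosal) fiber length
_INTRA_LENGTH_MM = 40.0           # baseline intrahemispheric fiber length
_LENGTH_JITTER = 0.20             # per-edge lognormal sigma on lengths
_INTRA_DENSITY = 0.35             # fraction of within-hemisphere pairs connected
_INTER_DENSITY = 0.10             # fraction of L-R cortical pairs connected
_CORTICAL_SHARE = 0.85            # share of streamline budget on cortical edges

# per-center demographics, loosely matching a 7-center MS cohort
_CENTER_N_PROP = np.array([221, 66, 62, 76, 86, 104, 82], dtype=float)
_AGE_HC = [(48.4, 9.3), (29.9, 10.6), (33.2, 7.0), (27.9, 6.4),
           (37.3, 9.3), (41.3, 11.6), (35.1, 8.7)]
_AGE_MS = [(48.8, 11.3), (48.8, 9.6), (34.4, 7.9), (35.8, 11.6),
           (42.2, 9.7), (42.5, 12.9), (40.6, 7.2)]
_FEMALE_HC = [0.58, 0.88, 0.63, 0.50, 0.40, 0.62, 0.63]
_FEMALE_MS = [0.72, 0.72, 0.63, 0.64, 0.55, 0.67, 0.71]

# nominal cross-subject scales used to size additive center shifts
_SCALAR_SCALES = {"cc_area": 80.0, "brain_volume": 1.0e5,
                  "gmf": 0.03, "wmf": 0.02, "lvf": 0.005}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    n_subjects: int = 697
    ms_fraction: float = 0.70
    n_centers: int = 7
    n_cortical_per_hemi: int = 30
    n_subcortical: int = 16
    total_streamlines: int = 10_000
    conservation_coupling: float = -0.4
    disease_effect_inter: float = 0.4
    site_shift_sd: float = 0.3
    site_scale_sd: float = 0.15
    noise_sd: float = 0.15
    seed: int = 0

    def validate(self) -> "CohortConfig":
        for name in ("n_subjects", "n_centers", "n_cortical_per_hemi",
                     "n_subcortical", "total_streamlines"):
            if int(getattr(self, name)) <= 0 and name != "n_subcortical":
                raise ValueError(f"{name} must be positive")
        for name in ("ms_fraction", "conservation_coupling",
                     "disease_effect_inter", "site_shift_sd",
                     "site_scale_sd", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")
        if not 0 < self.ms_fraction < 1:
            raise ValueError("ms_fraction must lie in (0, 1)")
        if not -1 <= self.conservation_coupling <= 1:
            raise ValueError("conservation_coupling must lie in [-1, 1]")
        if self.site_scale_sd < 0 or self.site_shift_sd < 0:
            raise ValueError("site effect magnitudes must be >= 0")
        if round(self.ms_fraction * self.n_subjects) < 1:
            raise ValueError("configuration yields no patients")
        return self


@dataclass
class SyntheticCohort:
    """Generated connectomes, subject table, and the planted ground truth."""

    connectomes: list[Connectome]
    records: pd.DataFrame
    ground_truth: dict

    def __post_init__(self) -> None:
        if len(self.connectomes) != len(self.records):
            raise ValueError("connectome list and record table lengths differ")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _region_table(n_cort: int, n_sub: int):
    labels, hemis, cort = [], [], []
    for h, tag in (("lh", "L"), ("rh", "R")):
        for i in range(n_cort):
            labels.append(f"ctx-{h}-{i + 1:03d}")
            hemis.append(tag)
            cort.append(True)
    for i in range(n_sub):
        labels.append(f"sub-{i + 1:03d}")
        # mostly lateralized subcortical structures plus a couple of midline ones
        hemis.append("M" if i >= n_sub - 2 else ("L" if i % 2 == 0 else "R"))
        cort.append(False)
    return labels, np.array(hemis, dtype=object), np.array(cort, dtype=bool)


def _intra_support(rng, offset: int, n: int) -> list[tuple[int, int]]:
    """Connected random support: random spanning tree plus extra edges."""
    perm = rng.permutation(n)
    edges = set()
    for k in range(1, n):
        a = perm[k]
        b = perm[rng.integers(0, k)]
        edges.add((min(a, b), max(a, b)))
    n_target = max(n - 1, int(round(_INTRA_DENSITY * n * (n - 1) / 2)))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    order = rng.permutation(len(pairs))
    for idx in order:
        if len(edges) >= n_target:
            break
        edges.add(pairs[idx])
    return [(offset + i, offset + j) for i, j in sorted(edges)]


def _tree_edges(edges: list[tuple[int, int]], n: int, offset: int) -> set[int]:
    """Indices (into edges) of a spanning forest, to be seeded with 1 streamline."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = set()
    for k, (i, j) in enumerate(edges):
        ri, rj = find(i - offset), find(j - offset)
        if ri != rj:
            parent[ri] = rj
            chosen.add(k)
    return chosen


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; bitwise deterministic given the seed."""
    config.validate()
    n = config.n_subjects
    n_cent = config.n_centers
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0)))

    # --- cohort-level structure -------------------------------------------
    n_ms = int(round(config.ms_fraction * n))
    is_ms = np.zeros(n, dtype=bool)
    is_ms[rng.permutation(n)[:n_ms]] = True

    props = _CENTER_N_PROP[np.arange(n_cent) % len(_CENTER_N_PROP)]
    centers = rng.choice(n_cent, size=n, p=props / props.sum())
    center_names = [f"center{c + 1:02d}" for c in range(n_cent)]

    u = rng.normal(size=n)
    s = np.zeros(n)
    sev = rng.normal(size=n)
    for _ in range(8):  # redraw out-of-range severities; [-2, 2] truncation
        bad = np.abs(sev) > 2
        if not bad.any():
            break
        sev[bad] = rng.normal(size=bad.sum())
    sev = np.clip(sev, -2, 2)
    s[is_ms] = sev[is_ms]

    # severity enters the interhemispheric logit relative to a disease
    # baseline (1 + s): being a patient lowers p_inter on average, and
    # higher severity lowers it further
    eps = rng.normal(scale=config.noise_sd, size=n)
    z = _CONS_SLOPE * u - config.disease_effect_inter * (1.0 + s) * is_ms + eps
    z_std = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros(n)
    rho = config.conservation_coupling
    v = rho * z_std + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
    p_inter = _logistic(_LOGIT_BASE + z)
    intra_factor = np.exp(_INTRA_STRENGTH_SD * v)

    # per-center batch effects
    site = {
        "log_scale_inter": rng.normal(scale=config.site_scale_sd, size=n_cent),
        "log_scale_intra": rng.normal(scale=config.site_scale_sd, size=n_cent),
        "scalar_log_scale": {k: rng.normal(scale=config.site_scale_sd, size=n_cent)
                             for k in _SCALAR_SCALES},
        "scalar_shift": {k: rng.normal(scale=config.site_shift_sd, size=n_cent)
                         for k in _SCALAR_SCALES},
    }

    # --- scalars and clinical scores --------------------------------------
    age = np.empty(n)
    sex = np.empty(n, dtype=int)
    for c in range(n_cent):
        ci = c % len(_AGE_HC)
        for ms_flag, age_tab, fem_tab in ((False, _AGE_HC, _FEMALE_HC),
                                          (True, _AGE_MS, _FEMALE_MS)):
            m = (centers == c) & (is_ms == ms_flag)
            if not m.any():
                continue
            mu, sd = age_tab[ci]
            age[m] = np.clip(rng.normal(mu, sd, size=m.sum()), 18, 85)
            sex[m] = rng.random(m.sum()) < fem_tab[ci]

    edss = np.full(n, np.nan)
    sdmt = np.full(n, np.nan)
    dd = np.full(n, np.nan)
    edss[is_ms] = np.clip(2.8 + 1.6 * s[is_ms] + rng.normal(scale=0.7, size=n_ms), 0, 10)
    edss[is_ms] = np.round(edss[is_ms] * 2) / 2
    sdmt[is_ms] = np.clip(np.round(50 - 9 * s[is_ms] + rng.normal(scale=7, size=n_ms)), 0, 120)
    dd[is_ms] = np.clip(rng.normal(11 + 2 * s[is_ms], 8), 0.2, 45)

    brain_volume = np.clip(rng.normal(1.5e6, 1.0e5, size=n), 8e5, None)
    # CC area tracks the interhemispheric share only loosely: it is a
    # volumetric proxy for one commissural system, not the tract count
    cc_area = 600.0 * (p_inter / 0.2) * np.exp(rng.normal(scale=0.5, size=n))
    gmf = np.clip(0.45 - 0.012 * s * is_ms + rng.normal(scale=0.02, size=n), 0.2, 0.7)
    wmf = np.clip(0.33 + 0.25 * (p_inter - p_inter.mean())
                  + rng.normal(scale=0.015, size=n), 0.1, 0.6)
    lvf = np.zeros(n)
    lvf[is_ms] = np.clip(np.exp(-5.2 + 0.9 * s[is_ms]
                                + rng.normal(scale=0.4, size=n_ms)), 1e-5, 0.2)

    # apply center scale x shift to the volumetric scalars
    scalars = {"cc_area": cc_area, "brain_volume": brain_volume,
               "gmf": gmf, "wmf": wmf, "lvf": lvf}
    for name, vals in scalars.items():
        sc = np.exp(site["scalar_log_scale"][name])[centers]
        sh = site["scalar_shift"][name][centers] * _SCALAR_SCALES[name]
        vals = vals * sc + sh
        if name in ("gmf", "wmf", "lvf"):
            vals = np.clip(vals, 0.0, 1.0)
        else:
            vals = np.clip(vals, 1e-6, None)
        scalars[name] = vals
    scalars["lvf"][~is_ms] = 0.0

    # --- connectomes -------------------------------------------------------
    labels, hemis, cortical = _region_table(config.n_cortical_per_hemi,
                                            config.n_subcortical)
    n_cort = config.n_cortical_per_hemi
    connectomes = []
    for j in range(n):
        srng = np.random.default_rng(np.random.SeedSequence((int(config.seed), j + 1)))
        connectomes.append(_subject_connectome(
            srng, labels, hemis, cortical, n_cort, config,
            p_inter[j], intra_factor[j],
            np.exp(site["log_scale_inter"][centers[j]]),
            np.exp(site["log_scale_intra"][centers[j]]),
        ))

    ids = [f"sub-{j + 1:04d}" for j in range(n)]
    records = pd.DataFrame({
        "id": ids,
        "center": [center_names[c] for c in centers],
        "age": np.round(age, 2),
        "sex": sex,
        "diagnosis": np.where(is_ms, "MS", "HC"),
        "edss": edss,
        "sdmt": sdmt,
        "disease_duration": np.round(dd, 2),
        "gmf": scalars["gmf"],
        "wmf": scalars["wmf"],
        "lvf": scalars["lvf"],
        "cc_area": scalars["cc_area"],
        "brain_volume": scalars["brain_volume"],
    }).set_index("id")

    ground_truth = {
        "config": asdict(config),
        "center_names": center_names,
        "subjects": {
            ids[j]: {
                "u": float(u[j]), "s": float(s[j]), "z": float(z[j]),
                "v": float(v[j]), "p_inter": float(p_inter[j]),
                "intra_strength": float(intra_factor[j]),
                "center": center_names[centers[j]],
                "is_ms": bool(is_ms[j]),
            } for j in range(n)
        },
        "centers": {
            center_names[c]: {
                "log_scale_inter": float(site["log_scale_inter"][c]),
                "log_scale_intra": float(site["log_scale_intra"][c]),
                "scalar_log_scale": {k: float(site["scalar_log_scale"][k][c])
                                     for k in _SCALAR_SCALES},
                "scalar_shift": {k: float(site["scalar_shift"][k][c])
                                 for k in _SCALAR_SCALES},
            } for c in range(n_cent)
        },
    }
    return SyntheticCohort(connectomes=connectomes, records=records,
                           ground_truth=ground_truth)


def _subject_connectome(rng, labels, hemis, cortical, n_cort, config,
                        p_inter, intra_factor, scale_inter, scale_intra):
    n_regions = len(labels)
    n_sub = n_regions - 2 * n_cort
    # supports
    left = _intra_support(rng, 0, n_cort)
    right = _intra_support(rng, n_cort, n_cort)
    n_inter = max(1, int(round(_INTER_DENSITY * n_cort * n_cort)))
    chosen = rng.choice(n_cort * n_cort, size=n_inter, replace=False)
    inter = [(int(k // n_cort), n_cort + int(k % n_cort)) for k in chosen]
    sub_edges = []
    for si in range(n_sub):
        node = 2 * n_cort + si
        targets = rng.choice(2 * n_cort, size=min(4, 2 * n_cort), replace=False)
        sub_edges += [(min(node, int(t)), max(node, int(t))) for t in targets]
    sub_edges = sorted(set(sub_edges))

    total = config.total_streamlines
    t_cort = int(round(_CORTICAL_SHARE * total)) if n_sub else total
    t_sub = total - t_cort

    blocks = [(inter, p_inter, True), (left, (1 - p_inter) / 2, False),
              (right, (1 - p_inter) / 2, False)]
    edge_list, probs, seeded = [], [], []
    for edges, share, _ in blocks:
        g = rng.gamma(shape=2.0, scale=1.0, size=len(edges))
        g = g / g.sum() * share
        edge_list += edges
        probs += list(g)
    # seed spanning trees with one streamline so hemispheres stay connected
    seed_idx = set()
    off = len(inter)
    for edges, offset in ((left, 0), (right, n_cort)):
        tree = _tree_edges(edges, n_cort, offset)
        seed_idx |= {off + k for k in tree}
        off += len(edges)
    n_seed = len(seed_idx)
    probs = np.asarray(probs)
    counts = rng.multinomial(max(t_cort - n_seed, 0), probs / probs.sum()).astype(float)
    for k in seed_idx:
        counts[k] += 1

    weights = np.zeros((n_regions, n_regions))
    lengths = np.zeros((n_regions, n_regions))
    intra_len = _INTRA_LENGTH_MM / intra_factor
    for (i, j), c_ij, is_inter in zip(
            edge_list, counts, [True] * len(inter) + [False] * (len(left) + len(right))):
        if c_ij <= 0:
            continue
        base = _INTER_LENGTH_MM if is_inter else intra_len
        ln = base * np.exp(rng.normal(scale=_LENGTH_JITTER))
        w = c_ij * (scale_inter if is_inter else scale_intra)
        weights[i, j] = weights[j, i] = w
        lengths[i, j] = lengths[j, i] = ln

    if t_sub > 0 and sub_edges:
        g = rng.gamma(2.0, 1.0, size=len(sub_edges))
        sub_counts = rng.multinomial(t_sub, g / g.sum()).astype(float)
        for (i, j), c_ij in zip(sub_edges, sub_counts):
            if c_ij <= 0:
                continue
            ln = 55.0 * np.exp(rng.normal(scale=_LENGTH_JITTER))
            weights[i, j] = weights[j, i] = c_ij * scale_intra
            lengths[i, j] = lengths[j, i] = ln

    return Connectome(labels=labels, hemisphere=hemis, cortical=cortical,
                      weights=weights, lengths=lengths)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write a cohort to disk; returns the manifest. See :mod:`hemiconn.io`."""
    return hio.write_cohort(cohort, directory)
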
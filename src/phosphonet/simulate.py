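"""Synthetic phosphoproteomic cohort generator with full ground truth.

The generator emulates the data model the downstream analysis assumes: each
phosphosite's raw intensity is the product of its parent protein's abundance
(shared across all sites of that protein — the confound protein correction is
meant to remove), a site-specific stoichiometry offset, a kinase-driven group
effect on substrate sites, and log-normal measurement noise.  Values are
generated on the log2 scale and exponentiated, so raw intensities are
log-normal.  Missing values are introduced either completely at random (MCAR)
or with a logistic dependence on latent log2 intensity (the usual
missing-not-at-random behaviour of label-free data, where low-abundance
signals drop out first).

Substrate sites of each simulated kinase carry that kinase's consensus motif
in their sequence windows at a configurable prevalence; background windows are
drawn from a uniform amino-acid alphabet.  Every planted quantity — site to
kinase assignments, per-(site, group) log2 shifts, expression-pattern labels
and the true differential sites of every comparison — is returned as ground
truth so each pipeline stage can be tested without real data.

The default cohort mirrors a pooled four-group autoimmune design: 15 healthy
control (HC), 14 stable lupus (SLE_S), 7 active lupus (SLE_A) and 16
rheumatoid arthritis (RA) sample pools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, SampleDesign, make_site_id

logger = logging.getLogger("phosphonet")

DEFAULT_GROUP_SIZES = {"HC": 15, "SLE_S": 14, "SLE_A": 7, "RA": 16}

#: residue frequencies of phosphoacceptor centres typical of S/T/Y data
CENTER_FREQS = {"S": 0.86, "T": 0.12, "Y": 0.02}


@dataclass(frozen=True)
class MotifSpec:
    """A kinase recognition motif: offset -> required residue around the site.

    Offsets are relative to the phosphoresidue (negative = N-terminal);
    offset 0 is reserved for the centre and may not appear in ``consensus``.
    """

    consensus: dict[int, str]
    prevalence: float = 0.8
    center: str = "S"

    def __post_init__(self) -> None:
        if 0 in self.consensus:
            raise ValueError(
                "consensus may not constrain offset 0: the centre residue is "
                f"fixed to the phosphoacceptor {self.center!r}"
            )
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.center not in "STY":
            raise ValueError(f"centre must be S, T or Y, got {self.center!r}")
        for off, res in self.consensus.items():
            if res not in AMINO_ACIDS:
                raise ValueError(f"consensus residue {res!r} at offset {off} is not an amino acid")


def _default_kinase_effects() -> dict[tuple[str, str], float]:
    # five expression patterns across (HC, SLE_S, SLE_A, RA): up in all
    # disease, up in active lupus only, down in disease, down in active lupus
    # only, and flat (K5 has no entry)
    return {
        ("K1", "SLE_S"): 1.0, ("K1", "SLE_A"): 1.0, ("K1", "RA"): 1.0,
        ("K2", "SLE_A"): 1.0,
        ("K3", "SLE_S"): -1.0, ("K3", "SLE_A"): -1.0, ("K3", "RA"): -1.0,
        ("K4", "SLE_A"): -1.0,
        ("K6", "SLE_S"): 1.0, ("K6", "SLE_A"): 1.0,
    }


def _default_motif_specs() -> dict[str, MotifSpec]:
    # canonical kinase classes: basophilic (RRxS), proline-directed (S-P),
    # acidophilic (SxxE-type), and mixed variants
    return {
        "K1": MotifSpec({-3: "R", -2: "R"}),
        "K2": MotifSpec({+1: "P"}),
        "K3": MotifSpec({+1: "D", +3: "E"}),
        "K4": MotifSpec({-3: "K", +1: "P"}),
        "K5": MotifSpec({-5: "L", -3: "R"}),
        "K6": MotifSpec({+1: "P", +2: "P"}),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.  All effects and SDs are log2-scale."""

    n_proteins: int = 300
    sites_per_protein_mean: float = 3.0
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_kinases: int = 6
    substrates_per_kinase: int = 20
    kinase_effects: dict[tuple[str, str], float] = field(default_factory=_default_kinase_effects)
    protein_sd: float = 0.5
    protein_noise_sd: float = 0.1
    site_noise_sd: float = 0.3
    missing_rate: float = 0.1
    missing_mode: str = "MCAR"
    missing_steepness: float = 1.0
    motif_specs: dict[str, MotifSpec] = field(default_factory=_default_motif_specs)
    window_halfwidth: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if min(self.protein_sd, self.protein_noise_sd, self.site_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.missing_mode not in ("MCAR", "intensity-dependent"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")

    @property
    def kinases(self) -> list[str]:
        return [f"K{i + 1}" for i in range(self.n_kinases)]


@dataclass
class GroundTruth:
    """Everything that was planted, keyed so tests can check recovery."""

    site_kinase: dict[str, str | None]
    site_group_shift: dict[str, dict[str, float]]
    pattern_labels: dict[str, str]
    site_has_motif: dict[str, bool]
    groups: list[str]

    def differential_sites(self, group_a: str, group_b: str) -> dict[str, float]:
        """Planted log2 shifts (A minus B); only truly shifted sites appear."""
        out = {}
        for site, shifts in self.site_group_shift.items():
            d = shifts.get(group_a, 0.0) - shifts.get(group_b, 0.0)
            if d != 0.0:
                out[site] = d
        return out

    def substrates_of(self, kinase: str) -> set[str]:
        return {s for s, k in self.site_kinase.items() if k == kinase}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_kinase": self.site_kinase,
            "site_group_shift": self.site_group_shift,
            "pattern_labels": self.pattern_labels,
            "site_has_motif": self.site_has_motif,
            "groups": self.groups,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SampleDesign, dict[str, str], GroundTruth]:
    """Generate one cohort.

    Returns (site table, site intensity matrix, protein intensity matrix,
    sample design, protein sequences, ground truth).  Identical seeds give
    bit-identical outputs (NumPy PCG64 generator).
    """
    rng = np.random.default_rng(cfg.seed)
    h = cfg.window_halfwidth

    # --- samples ----------------------------------------------------------
    groups = list(cfg.group_sizes)
    mapping = {
        f"{g}_{i + 1:02d}": g for g in groups for i in range(cfg.group_sizes[g])
    }
    design = SampleDesign(mapping, group_order=groups)
    samples = design.samples

    # --- proteins, site placement ----------------------------------------
    protein_ids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    n_sites_per_protein = np.maximum(1, rng.poisson(cfg.sites_per_protein_mean, cfg.n_proteins))
    total_sites = int(n_sites_per_protein.sum())
    needed = cfg.n_kinases * cfg.substrates_per_kinase
    if needed > total_sites:
        raise ValueError(
            f"infeasible config: {cfg.n_kinases} kinases x {cfg.substrates_per_kinase} "
            f"substrates = {needed} exceeds {total_sites} total sites"
        )

    lengths = rng.integers(200, 601, cfg.n_proteins)
    seq_arrays = {
        pid: rng.integers(0, 20, n) for pid, n in zip(protein_ids, lengths)
    }
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    site_protein: list[str] = []
    site_pos: list[int] = []
    for pid, n_sites, length in zip(protein_ids, n_sites_per_protein, lengths):
        # keep sites away from the termini so planted motifs fit the window
        candidates = np.arange(h + 1, length - h + 1)
        pos = rng.choice(candidates, size=min(n_sites, len(candidates)), replace=False)
        for p in np.sort(pos):
            site_protein.append(pid)
            site_pos.append(int(p))
    n_total = len(site_protein)

    # --- kinase assignment ------------------------------------------------
    order = rng.permutation(n_total)
    site_kinase: list[str | None] = [None] * n_total
    for ki, kin in enumerate(cfg.kinases):
        for j in order[ki * cfg.substrates_per_kinase : (ki + 1) * cfg.substrates_per_kinase]:
            site_kinase[j] = kin

    # --- centre residues and planted motifs -------------------------------
    center_letters = rng.choice(
        list(CENTER_FREQS), size=n_total, p=list(CENTER_FREQS.values())
    )
    site_has_motif = [False] * n_total
    for j in range(n_total):
        kin = site_kinase[j]
        if kin is None or kin not in cfg.motif_specs:
            continue
        spec = cfg.motif_specs[kin]
        center_letters[j] = spec.center
        if rng.random() < spec.prevalence:
            site_has_motif[j] = True
            arr = seq_arrays[site_protein[j]]
            for off, res in spec.consensus.items():
                arr[site_pos[j] - 1 + off] = aa_index[res]
    # centres written last so overlapping motif flanks cannot clobber them
    for j in range(n_total):
        seq_arrays[site_protein[j]][site_pos[j] - 1] = aa_index[center_letters[j]]
    seqs = {pid: "".join(AMINO_ACIDS[i] for i in arr) for pid, arr in seq_arrays.items()}

    site_ids = [
        make_site_id(pid, res, pos)
        for pid, res, pos in zip(site_protein, center_letters, site_pos)
    ]

    # --- quantitative model ----------------------------------------------
    n_samples = len(samples)
    base = rng.normal(22.0, 2.0, cfg.n_proteins)  # overall protein log2 level
    dev = rng.normal(0.0, cfg.protein_sd, (cfg.n_proteins, n_samples))  # per-sample abundance
    protein_log2 = base[:, None] + dev + rng.normal(0.0, cfg.protein_noise_sd, (cfg.n_proteins, n_samples))

    prot_index = {pid: i for i, pid in enumerate(protein_ids)}
    site_offset = rng.normal(0.0, 1.0, n_total)
    group_of = np.array([mapping[s] for s in samples])

    effect = np.zeros((n_total, n_samples))
    shifts: dict[str, dict[str, float]] = {}
    for j, (sid, kin) in enumerate(zip(site_ids, site_kinase)):
        per_group = {}
        if kin is not None:
            for g in groups:
                e = cfg.kinase_effects.get((kin, g), 0.0)
                if e != 0.0:
                    per_group[g] = e
                    effect[j, group_of == g] = e
        shifts[sid] = per_group

    prot_rows = np.array([prot_index[p] for p in site_protein])
    latent = (
        base[prot_rows][:, None]
        + dev[prot_rows]
        + site_offset[:, None]
        + effect
        + rng.normal(0.0, cfg.site_noise_sd, (n_total, n_samples))
    )

    site_raw = 2.0 ** latent
    protein_raw = 2.0 ** protein_log2

    # --- missingness ------------------------------------------------------
    if cfg.missing_rate > 0:
        if cfg.missing_mode == "MCAR":
            mask = rng.random(latent.shape) < cfg.missing_rate
        else:
            # logistic in latent log2 intensity, centred on the median so the
            # overall expected rate stays close to missing_rate
            from scipy.special import expit

            mid = np.median(latent)
            p = np.clip(
                2.0 * cfg.missing_rate * expit(-(latent - mid) / cfg.missing_steepness),
                0.0, 1.0,
            )
            mask = rng.random(latent.shape) < p
        site_raw = np.where(mask, np.nan, site_raw)

    site_matrix = pd.DataFrame(site_raw, index=pd.Index(site_ids, name="site_id"), columns=samples)
    protein_matrix = pd.DataFrame(
        protein_raw, index=pd.Index(protein_ids, name="protein_id"), columns=samples
    )

    # --- site table with windows -----------------------------------------
    windows = []
    for pid, pos in zip(site_protein, site_pos):
        seq = seqs[pid]
        left = seq[max(0, pos - 1 - h) : pos - 1]
        right = seq[pos : pos + h]
        windows.append("X" * (h - len(left)) + left + seq[pos - 1] + right + "X" * (h - len(right)))
    site_table = pd.DataFrame(
        {
            "site_id": site_ids,
            "protein_id": site_protein,
            "residue": center_letters,
            "position": site_pos,
            "window": windows,
        }
    )

    pattern_labels = {
        sid: "|".join(f"{g}:{shifts[sid].get(g, 0.0):+g}" for g in groups if shifts[sid].get(g, 0.0))
        or "flat"
        for sid in site_ids
    }
    truth = GroundTruth(
        site_kinase=dict(zip(site_ids, site_kinase)),
        site_group_shift=shifts,
        pattern_labels=pattern_labels,
        site_has_motif=dict(zip(site_ids, site_has_motif)),
        groups=groups,
    )
    return site_table, site_matrix, protein_matrix, design, seqs, truth


def random_window(rng: np.random.Generator, h: int, center: str) -> str:
    flanks = rng.integers(0, 20, 2 * h)
    left = "".join(AMINO_ACIDS[i] for i in flanks[:h])
    right = "".join(AMINO_ACIDS[i] for i in flanks[h:])
    return left + center + right


def _matches(window: str, consensus: dict[int, str], h: int) -> bool:
    return all(window[h + off] == res for off, res in consensus.items())


def planted_motif_windows(
    spec: MotifSpec, n_fg: int, n_bg: int, h: int = 6, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Generate foreground windows with a planted consensus and a uniform background.

    Exactly ``round(prevalence * n_fg)`` foreground windows match the full
    consensus; the remaining foreground windows are guaranteed NOT to match it
    (one consensus position is mutated if a random draw matches by chance), so
    the planted match count is exact by construction.  Background windows are
    uniform draws and match only at chance rate.
    """
    if any(abs(off) > h for off in spec.consensus):
        raise ValueError("consensus offsets exceed the window half-width")
    rng = np.random.default_rng(seed)
    n_match = round(spec.prevalence * n_fg)
    fg: list[str] = []
    for i in range(n_fg):
        w = random_window(rng, h, spec.center)
        chars = list(w)
        if i < n_match:
            for off, res in spec.consensus.items():
                chars[h + off] = res
        elif spec.consensus and _matches("".join(chars), spec.consensus, h):
            off = next(iter(spec.consensus))
            res = spec.consensus[off]
            alternatives = [a for a in AMINO_ACIDS if a != res]
            chars[h + off] = alternatives[int(rng.integers(0, len(alternatives)))]
        fg.append("".join(chars))
    bg = [random_window(rng, h, spec.center) for _ in range(n_bg)]
    return fg, bg


def synthetic_pathway_sets(
    site_table: pd.DataFrame,
    truth: GroundTruth,
    n_random_terms: int = 20,
    term_size: int = 15,
    seed: int = 0,
) -> dict[str, tuple[str, set[str]]]:
    """Protein-level term sets for testing enrichment end to end.

    One term per kinase groups the proteins of its substrates (enriched by
    construction wherever that kinase drives a group effect), plus random
    protein sets as unenriched decoys.
    """
    rng = np.random.default_rng(seed)
    by_site = site_table.set_index("site_id")["protein_id"]
    terms: dict[str, tuple[str, set[str]]] = {}
    kinases = sorted({k for k in truth.site_kinase.values() if k is not None})
    for kin in kinases:
        members = {by_site[s] for s in truth.substrates_of(kin)}
        if members:
            terms[f"PATH_{kin}"] = (f"substrate proteins of {kin}", members)
    proteins = sorted(set(by_site))
    for i in range(n_random_terms):
        size = min(term_size, len(proteins))
        members = set(rng.choice(proteins, size=size, replace=False))
        terms[f"PATH_R{i + 1:02d}"] = (f"random protein set {i + 1}", members)
    return terms
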
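"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a two-group (12 NZ / 14 non-NZ
subjects, pooled into 3 + 5 labeled iTRAQ channels) seminal-plasma EV
proteomics study: per-site ground-truth Cit/hCit stoichiometries that differ
between groups, isobaric confound modifications (deamidation of Asn/Gln,
peptide N-terminal carbamylation), Poisson spectral counts, lognormal
reporter intensities, and clinical covariates with a configurable negative
correlation between hCit burden and morphology/motility.

Modification events are Bernoulli per PSM, so site stoichiometry is binomial
at the PSM level — the same sampling unit the intensity-ratio estimator
uses.  Reporter intensity is emitted in the PSM's own pool channel on a
scale of about one unit per PSM, so intensity totals and spectral counts
live on the same scale.  The clinical correlation uses a shared latent
factor: morphology and motility are linear in the cohort-standardized latent
hCit burden plus independent Gaussian noise, so the cohort-level Pearson
correlation equals the configured target and the group difference in those
two variables emerges through the burden gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .io_formats import (ClinicalRecord, DomainAnnotation, PSMRecord,
                         ReporterDesign, write_clinical, write_domains,
                         write_fasta, write_marker_list, write_psm_table)
from .upm_annotation import DELTA_CARBAMYL, DELTA_CIT

_AA_POOL = "ACDEFGHIKLMNPQSTVWY"  # R excluded; R is placed only at Cit sites


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSpec:
    """A ground-truth modifiable site: R carries Cit, K carries hCit."""

    position: int  # 1-based
    residue: str  # "R" or "K"
    stoichiometry: Mapping[str, float]  # group -> true modified fraction

    def __post_init__(self):
        if self.residue not in ("R", "K"):
            raise ValueError("site residue must be R (Cit) or K (hCit)")
        for g, f in self.stoichiometry.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"stoichiometry {f} for group {g} outside [0, 1]")

    @property
    def delta(self) -> float:
        return DELTA_CIT if self.residue == "R" else DELTA_CARBAMYL


@dataclass(frozen=True)
class ProteinSpec:
    accession: str
    length: int
    abundance: float = 1.0
    sites: Tuple[SiteSpec, ...] = ()
    category: Optional[str] = None
    marker_class: Optional[str] = None  # "exosome" | "microvesicle" | None
    group_abundance: Optional[Mapping[str, float]] = None  # per-group multiplier
    n_background_peptides: int = 2

    def __post_init__(self):
        if self.length < 15:
            raise ValueError("protein length must be >= 15")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        for s in self.sites:
            if not 1 <= s.position <= self.length:
                raise ValueError(
                    f"site position {s.position} outside protein {self.accession}")


@dataclass(frozen=True)
class ClinicalSimConfig:
    """Clinical covariate model.

    Percent units for vitality/morphology/motility, 10^6/ml for count, years
    for age.  Vitality and count carry explicit NZ vs nonNZ mean shifts;
    morphology and motility inherit their group difference through the
    latent hCit burden so the configured burden correlation holds
    cohort-wide.
    """

    burden_mean: Mapping[str, float] = field(
        default_factory=lambda: {"NZ": 1.0, "nonNZ": 1.8})
    burden_sd: float = 0.2
    r_hcit: float = -0.6  # target Pearson(burden, morphology) = (burden, motility)
    morphology_base: float = 6.0
    morphology_sd: float = 2.5
    motility_base: float = 40.0
    motility_sd: float = 12.0
    vitality_mean: Mapping[str, float] = field(
        default_factory=lambda: {"NZ": 75.0, "nonNZ": 58.0})
    vitality_sd: float = 9.0
    count_mean: Mapping[str, float] = field(
        default_factory=lambda: {"NZ": 80.0, "nonNZ": 35.0})
    count_sd: float = 20.0
    age_mean: float = 35.0
    age_sd: float = 5.0
    flag_rates: Mapping[str, float] = field(
        default_factory=lambda: {"smoking": 0.3, "alcohol": 0.4, "toxicology": 0.08})

    def __post_init__(self):
        if not abs(self.r_hcit) < 1:
            raise ValueError("|r_hcit| must be < 1")
        for name in ("burden_sd", "morphology_sd", "motility_sd",
                     "vitality_sd", "count_sd", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_nz_subjects: int = 12
    n_nonnz_subjects: int = 14
    design: ReporterDesign = field(default_factory=ReporterDesign)
    proteins: Tuple[ProteinSpec, ...] = ()
    psm_rate: float = 12.0  # mean spectral counts per peptide per pool (Poisson)
    reporter_sigma: float = 0.3  # lognormal sigma of per-PSM reporter intensity
    intensity_scale: float = 1.0  # reporter units per PSM (before noise)
    deamidation_rate: float = 0.05  # per PSM, applied to a random N/Q if present
    nterm_carbamyl_rate: float = 0.02  # per PSM
    decoy_fraction: float = 0.03  # PSMs given q above the 1% identification cut
    peptide_length: int = 12
    clinical: ClinicalSimConfig = field(default_factory=ClinicalSimConfig)

    def __post_init__(self):
        if self.psm_rate <= 0 or self.reporter_sigma <= 0 or self.intensity_scale <= 0:
            raise ValueError("rates and scales must be positive")
        for name in ("deamidation_rate", "nterm_carbamyl_rate", "decoy_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_nz_subjects < 2 or self.n_nonnz_subjects < 2:
            raise ValueError("need at least 2 subjects per group")

    def with_roster(self, proteins: Sequence[ProteinSpec]) -> "SimulationConfig":
        from dataclasses import replace
        return replace(self, proteins=tuple(proteins))


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery tests: keyed by (accession, position)."""

    site_stoichiometry: Mapping[Tuple[str, int], Mapping[str, float]]
    cumulative_hcit_rate: Mapping[str, float]  # expected hCit spectral counts
    subject_burden: Mapping[str, float]
    clinical_means: Mapping[str, Mapping[str, float]]


@dataclass(frozen=True)
class SimulatedData:
    psms: Tuple[PSMRecord, ...]
    sequences: Mapping[str, str]
    domains: Tuple[DomainAnnotation, ...]
    markers: Tuple[str, ...]
    exosome_markers: Tuple[str, ...]
    microvesicle_markers: Tuple[str, ...]
    clinical: Tuple[ClinicalRecord, ...]
    categories: Mapping[str, str]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# default study roster
# ---------------------------------------------------------------------------

def default_roster() -> Tuple[ProteinSpec, ...]:
    """The default protein roster: eight citrullinated seminal-plasma EV
    proteins with group-specific site stoichiometries, hCit carriers with a
    nonNZ-elevated carbamylation rate, and common EV-marker proteins."""

    def cit(pos, nz, nonnz):
        return SiteSpec(pos, "R", {"NZ": nz, "nonNZ": nonnz})

    def hcit(pos, nz, nonnz):
        return SiteSpec(pos, "K", {"NZ": nz, "nonNZ": nonnz})

    return (
        ProteinSpec("SEMG2_HUMAN", 582, 1.2,
                    (cit(245, 0.3175, 0.2900), hcit(279, 0.05, 0.16)),
                    category="Eppin protein complex"),
        ProteinSpec("DPP4_HUMAN", 766, 1.0, (cit(611, 0.266, 0.233),),
                    category="sperm motility"),
        ProteinSpec("HSP7C_HUMAN", 646, 1.0,
                    (cit(155, 0.407, 0.383), hcit(512, 0.06, 0.14)),
                    category="sperm motility"),
        ProteinSpec("TGM4_HUMAN", 684, 0.9, (cit(393, 0.767, 0.761),),
                    category="semen viscosity"),
        ProteinSpec("ANXA2_HUMAN", 339, 1.1, (cit(196, 0.244, 0.234),),
                    category="sperm viability", marker_class="exosome"),
        ProteinSpec("CBPE_HUMAN", 476, 0.8, (cit(374, 0.528, 0.477),),
                    category="others"),
        ProteinSpec("C9JKZ3", 492, 0.7, (cit(409, 0.172, 0.146),),
                    category="sperm motility"),
        ProteinSpec("RAB27A_HUMAN", 221, 1.0, (cit(80, 0.301, 0.313),),
                    category="sperm exocytosis", marker_class="exosome"),
        ProteinSpec("LTF_HUMAN", 710, 0.9, (cit(121, 0.25, 0.25),),
                    category="inflammatory moderators"),
        ProteinSpec("SEMG1_HUMAN", 462, 1.3, (hcit(90, 0.05, 0.15),),
                    category="Eppin protein complex"),
        ProteinSpec("EPPIN_HUMAN", 133, 0.8, (hcit(45, 0.04, 0.12),),
                    category="others"),
        # EV-marker background proteins (exosome markers more abundant than
        # microvesicle markers, as in exosome-dominated sEV preparations)
        ProteinSpec("CD9_HUMAN", 228, 2.0, marker_class="exosome"),
        ProteinSpec("CD63_HUMAN", 238, 1.8, marker_class="exosome"),
        ProteinSpec("CD81_HUMAN", 236, 1.6, marker_class="exosome"),
        ProteinSpec("TSG101_HUMAN", 390, 1.4, marker_class="exosome"),
        ProteinSpec("PDCD6IP_HUMAN", 868, 1.5, marker_class="exosome"),
        ProteinSpec("FLOT1_HUMAN", 427, 0.8, marker_class="microvesicle"),
        ProteinSpec("ANXA1_HUMAN", 346, 0.7, marker_class="microvesicle"),
        ProteinSpec("ITGB1_HUMAN", 798, 0.6, marker_class="microvesicle"),
    )


def default_domains() -> Tuple[DomainAnnotation, ...]:
    return (
        DomainAnnotation("SEMG2_HUMAN", "Intrinsically disordered region", 228, 248),
        DomainAnnotation("DPP4_HUMAN", "Prolyl endopeptidase motif", 605, 635),
        DomainAnnotation("CBPE_HUMAN", "Peptidase-associated domain", 320, 420),
        DomainAnnotation("TGM4_HUMAN", "Transglutaminase catalytic domain", 276, 580),
    )


#: Accessions listed in the marker file but intentionally absent from the
#: roster, to exercise the "not detected" path.
_ABSENT_MARKERS = ("HSPA5_HUMAN", "ENO1_HUMAN", "SELP_HUMAN")


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed, proteins=default_roster())


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _make_sequence(rng: np.random.Generator, spec: ProteinSpec) -> str:
    seq = list(rng.choice(list(_AA_POOL), size=spec.length))
    for site in spec.sites:
        seq[site.position - 1] = site.residue
    return "".join(seq)


def _site_peptide(spec: ProteinSpec, site: SiteSpec, length: int) -> Tuple[int, int]:
    """(peptide_start, site offset) for the peptide covering *site*."""
    start = min(max(1, site.position - length // 2 + 1),
                spec.length - length + 1)
    return start, site.position - start


def _background_starts(spec: ProteinSpec, length: int) -> List[int]:
    """Deterministic background peptide starts avoiding all site positions."""
    taken = {s.position for s in spec.sites}
    starts: List[int] = []
    pos = 1
    while len(starts) < spec.n_background_peptides and pos + length - 1 <= spec.length:
        window = range(pos, pos + length)
        if not taken.intersection(window):
            starts.append(pos)
        pos += length + 5
    return starts


def _emit_peptide(rng: np.random.Generator, config: SimulationConfig,
                  spec: ProteinSpec, peptide: str, start: int,
                  site: Optional[SiteSpec], site_offset: Optional[int],
                  counter: List[int], out: List[PSMRecord]) -> None:
    design = config.design
    nq_offsets = [i for i, aa in enumerate(peptide) if aa in "NQ"]
    for channel in design.pools:  # pools in fixed channel order
        pool = channel
        group = design.pool_group(pool)
        mult = 1.0
        if spec.group_abundance:
            mult = spec.group_abundance.get(group, 1.0)
        n = rng.poisson(config.psm_rate * spec.abundance * mult)
        if n == 0:
            continue
        if site is not None:
            p_mod = site.stoichiometry.get(group, 0.0)
            modified = rng.random(n) < p_mod
        else:
            modified = np.zeros(n, dtype=bool)
        deamidated = (rng.random(n) < config.deamidation_rate) if nq_offsets \
            else np.zeros(n, dtype=bool)
        deam_pick = rng.integers(0, len(nq_offsets), size=n) if nq_offsets \
            else np.zeros(n, dtype=int)
        carbamylated = rng.random(n) < config.nterm_carbamyl_rate
        decoy = rng.random(n) < config.decoy_fraction
        q_good = rng.uniform(0.0, 0.009, size=n)
        q_bad = rng.uniform(0.011, 0.3, size=n)
        intensity = config.intensity_scale * rng.lognormal(
            0.0, config.reporter_sigma, size=n)
        own_channel = config.design.pool_to_channel[pool]
        for i in range(n):
            mods: List[Tuple[int, float]] = []
            if site is not None and modified[i]:
                mods.append((site_offset, site.delta))
            if deamidated[i]:
                off = nq_offsets[deam_pick[i]]
                if not (site is not None and modified[i] and off == site_offset):
                    mods.append((off, DELTA_CIT))
            if carbamylated[i]:
                mods.append((-1, DELTA_CARBAMYL))
            counter[0] += 1
            out.append(PSMRecord(
                spectrum_id=f"sp{counter[0]:07d}",
                peptide=peptide,
                protein_accession=spec.accession,
                peptide_start=start,
                mods=tuple(mods),
                q_value=float(q_bad[i] if decoy[i] else q_good[i]),
                reporter_intensities={own_channel: float(intensity[i])},
                pool_id=pool,
            ))


def _simulate_psms(rng: np.random.Generator, config: SimulationConfig,
                   sequences: Mapping[str, str]) -> List[PSMRecord]:
    out: List[PSMRecord] = []
    counter = [0]
    for spec in config.proteins:
        seq = sequences[spec.accession]
        for site in spec.sites:
            start, offset = _site_peptide(spec, site, config.peptide_length)
            peptide = seq[start - 1:start - 1 + config.peptide_length]
            _emit_peptide(rng, config, spec, peptide, start, site, offset,
                          counter, out)
        for start in _background_starts(spec, config.peptide_length):
            peptide = seq[start - 1:start - 1 + config.peptide_length]
            _emit_peptide(rng, config, spec, peptide, start, None, None,
                          counter, out)
    return out


def _simulate_clinical(rng: np.random.Generator, config: SimulationConfig
                       ) -> Tuple[List[ClinicalRecord], Dict[str, float],
                                  Dict[str, Dict[str, float]]]:
    c = config.clinical
    subjects = ([("NZ", f"NZ{i + 1:02d}") for i in range(config.n_nz_subjects)]
                + [("nonNZ", f"nonNZ{i + 1:02d}")
                   for i in range(config.n_nonnz_subjects)])
    n = len(subjects)
    groups = np.array([g for g, _ in subjects])
    burden = np.array([c.burden_mean[g] for g in groups]) \
        + c.burden_sd * rng.standard_normal(n)
    z = (burden - burden.mean()) / burden.std()
    r = c.r_hcit
    noise_scale = math.sqrt(1.0 - r * r)

    morphology = np.clip(
        c.morphology_base + c.morphology_sd * (r * z + noise_scale
                                               * rng.standard_normal(n)),
        0.0, 100.0)
    motility = np.clip(
        c.motility_base + c.motility_sd * (r * z + noise_scale
                                           * rng.standard_normal(n)),
        0.0, 100.0)
    vitality = np.clip(
        np.array([c.vitality_mean[g] for g in groups])
        + c.vitality_sd * rng.standard_normal(n), 0.0, 100.0)
    count = np.maximum(
        np.array([c.count_mean[g] for g in groups])
        + c.count_sd * rng.standard_normal(n), 0.5)
    age = np.round(np.clip(c.age_mean + c.age_sd * rng.standard_normal(n),
                           22.0, 50.0), 1)
    flags = {name: rng.random(n) < rate for name, rate in c.flag_rates.items()}

    records = []
    burden_map: Dict[str, float] = {}
    for i, (group, sid) in enumerate(subjects):
        records.append(ClinicalRecord(
            subject_id=sid, group=group,
            vitality=round(float(vitality[i]), 2),
            morphology=round(float(morphology[i]), 2),
            progressive_motility=round(float(motility[i]), 2),
            count=round(float(count[i]), 2),
            age=float(age[i]),
            smoking=bool(flags["smoking"][i]),
            alcohol=bool(flags["alcohol"][i]),
            toxicology=bool(flags["toxicology"][i]),
        ))
        burden_map[sid] = float(burden[i])
    means = {
        "vitality": dict(c.vitality_mean),
        "count": dict(c.count_mean),
        "burden": dict(c.burden_mean),
        "morphology_base": {"all": c.morphology_base},
        "motility_base": {"all": c.motility_base},
    }
    return records, burden_map, means


def _ground_truth(config: SimulationConfig, burden: Dict[str, float],
                  means: Dict[str, Dict[str, float]]) -> GroundTruth:
    site_truth = {}
    hcit_rate = {g: 0.0 for g in config.design.groups}
    for spec in config.proteins:
        for site in spec.sites:
            site_truth[(spec.accession, site.position)] = dict(site.stoichiometry)
            if site.residue == "K":
                for g in config.design.groups:
                    n_pools = len(config.design.channels_for(g))
                    hcit_rate[g] += (config.psm_rate * spec.abundance
                                     * site.stoichiometry.get(g, 0.0) * n_pools)
    return GroundTruth(
        site_stoichiometry=site_truth,
        cumulative_hcit_rate=hcit_rate,
        subject_burden=burden,
        clinical_means=means,
    )


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate the full in-memory bundle; deterministic given config.seed."""
    if not config.proteins:
        config = config.with_roster(default_roster())
    rng = np.random.default_rng(config.seed)
    sequences = {spec.accession: _make_sequence(rng, spec)
                 for spec in config.proteins}
    psms = _simulate_psms(rng, config, sequences)
    clinical, burden, means = _simulate_clinical(rng, config)

    roster_markers = [s.accession for s in config.proteins if s.marker_class]
    markers = tuple(roster_markers) + _ABSENT_MARKERS
    exosome = tuple(s.accession for s in config.proteins
                    if s.marker_class == "exosome")
    microvesicle = tuple(s.accession for s in config.proteins
                         if s.marker_class == "microvesicle") + ("SELP_HUMAN",)
    categories = {s.accession: s.category for s in config.proteins if s.category}
    domains = tuple(d for d in default_domains()
                    if d.protein_accession in sequences)
    return SimulatedData(
        psms=tuple(psms),
        sequences=sequences,
        domains=domains,
        markers=markers,
        exosome_markers=exosome,
        microvesicle_markers=microvesicle,
        clinical=tuple(clinical),
        categories=categories,
        ground_truth=_ground_truth(config, burden, means),
    )


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "psm": "psm.tsv",
    "fasta": "proteins.fasta",
    "domains": "domains.tsv",
    "markers": "markers.txt",
    "exosome_markers": "exosome_markers.txt",
    "microvesicle_markers": "microvesicle_markers.txt",
    "clinical": "clinical.csv",
    "categories": "categories.tsv",
    "manifest": "manifest.yaml",
}


def _write_categories(categories: Mapping[str, str], path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("protein_accession\tcategory\n")
        for acc in sorted(categories):
            fh.write(f"{acc}\t{categories[acc]}\n")


def _manifest_dict(config: SimulationConfig, data: SimulatedData) -> dict:
    gt = data.ground_truth
    return {
        "seed": config.seed,
        "n_subjects": {"NZ": config.n_nz_subjects, "nonNZ": config.n_nonnz_subjects},
        "psm_rate": config.psm_rate,
        "reporter_sigma": config.reporter_sigma,
        "r_hcit": config.clinical.r_hcit,
        "n_psms": len(data.psms),
        "site_stoichiometry": {
            f"{acc}:{pos}": {g: round(float(v), 6) for g, v in truth.items()}
            for (acc, pos), truth in sorted(gt.site_stoichiometry.items())},
        "cumulative_hcit_rate": {
            g: round(float(v), 6) for g, v in gt.cumulative_hcit_rate.items()},
        "subject_burden": {
            s: round(float(v), 6) for s, v in sorted(gt.subject_burden.items())},
        "clinical_means": {k: dict(v) for k, v in gt.clinical_means.items()},
    }


def simulate_dataset(config: SimulationConfig,
                     out_dir: str | Path) -> Tuple[Dict[str, Path], GroundTruth]:
    """Write the file bundle (PSM table, FASTA, domains, markers, clinical,
    categories, manifest) and return the paths and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = simulate(config)
    paths = {k: out_dir / v for k, v in BUNDLE_FILES.items()}
    write_psm_table(data.psms, paths["psm"])
    write_fasta(data.sequences, paths["fasta"])
    write_domains(data.domains, paths["domains"])
    write_marker_list(data.markers, paths["markers"],
                      comment="synthetic top EV markers")
    write_marker_list(data.exosome_markers, paths["exosome_markers"],
                      comment="synthetic exosome markers")
    write_marker_list(data.microvesicle_markers, paths["microvesicle_markers"],
                      comment="synthetic microvesicle markers")
    write_clinical(data.clinical, paths["clinical"])
    _write_categories(data.categories, paths["categories"])
    with paths["manifest"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(_manifest_dict(config, data), fh, sort_keys=True)
    return paths, data.ground_truth


# ---------------------------------------------------------------------------
# toy fixture
# ---------------------------------------------------------------------------

def _toy_sequence(length: int, overrides: Mapping[int, str]) -> str:
    base = ("GAVLIPFMWSTCYNQDEKH" * (length // 19 + 1))[:length]
    seq = list(base)
    for pos, aa in overrides.items():
        seq[pos - 1] = aa
    return "".join(seq)


def make_toy_data() -> SimulatedData:
    """A hand-checkable bundle: 46 PSMs, 3 proteins.

    Ground truth for the TOYA R10 Cit site after the q < 0.01 filter:
    NZ pools carry 2 modified + 3 unmodified PSMs each (intensity exactly 1
    in the pool's own channel), nonNZ pools 1 + 4, so stoichiometry is
    100*6/15 = 40.00 % in NZ and 100*5/25 = 20.00 % in nonNZ.  One
    deamidated Asn (+0.98402 on N) and one N-terminal carbamyl (+43.00581 at
    offset -1) PSM exercise the confound discrimination; one q = 0.5 PSM
    exercises the identification filter.  Every channel's intensity sum is
    positive.
    """
    design = ReporterDesign()
    sequences = {
        "TOYA": _toy_sequence(40, {10: "R", 22: "N"}),
        "TOYB": _toy_sequence(35, {8: "K"}),
        "TOYC": _toy_sequence(30, {}),
    }
    pep_a1 = sequences["TOYA"][5:17]   # positions 6-17, R10 at offset 4
    pep_a2 = sequences["TOYA"][19:31]  # positions 20-31, N22 at offset 2
    pep_b1 = sequences["TOYB"][2:14]   # positions 3-14, K8 at offset 5
    pep_c1 = sequences["TOYC"][0:12]

    psms: List[PSMRecord] = []
    counter = [0]

    def add(peptide, accession, start, mods, pool, q=0.001, intensity=1.0):
        counter[0] += 1
        channel = design.pool_to_channel[pool]
        psms.append(PSMRecord(
            spectrum_id=f"toy{counter[0]:03d}", peptide=peptide,
            protein_accession=accession, peptide_start=start, mods=tuple(mods),
            q_value=q, reporter_intensities={channel: intensity}, pool_id=pool))

    for pool in design.pools:
        is_nz = design.pool_group(pool) == "NZ"
        n_mod = 2 if is_nz else 1
        for _ in range(n_mod):
            add(pep_a1, "TOYA", 6, [(4, DELTA_CIT)], pool)
        for _ in range(5 - n_mod):
            add(pep_a1, "TOYA", 6, [], pool)
    add(pep_a2, "TOYA", 20, [(2, DELTA_CIT)], "NZ1")           # deamidated N22
    add(pep_a2, "TOYA", 20, [(-1, DELTA_CARBAMYL)], "nonNZ1")  # N-term carbamyl
    add(pep_b1, "TOYB", 3, [(5, DELTA_CARBAMYL)], "nonNZ2")    # hCit K8
    add(pep_b1, "TOYB", 3, [], "NZ2")
    add(pep_c1, "TOYC", 1, [], "nonNZ3")
    add(pep_a1, "TOYA", 6, [(4, DELTA_CIT)], "NZ1", q=0.5)     # fails the FDR filter

    config = SimulationConfig(seed=7, proteins=(
        ProteinSpec("TOYA", 40, sites=(SiteSpec(10, "R", {"NZ": 0.4, "nonNZ": 0.2}),)),
    ))
    rng = np.random.default_rng(config.seed)
    clinical, burden, means = _simulate_clinical(rng, config)

    truth = GroundTruth(
        site_stoichiometry={("TOYA", 10): {"NZ": 0.4, "nonNZ": 0.2},
                            ("TOYB", 8): {"NZ": 0.0, "nonNZ": 1.0}},
        cumulative_hcit_rate={"NZ": 0.0, "nonNZ": 1.0},
        subject_burden=burden,
        clinical_means=means,
    )
    return SimulatedData(
        psms=tuple(psms),
        sequences=sequences,
        domains=(DomainAnnotation("TOYA", "Toy domain", 5, 15),),
        markers=("TOYC", "ABSENT1"),
        exosome_markers=("TOYC",),
        microvesicle_markers=("ABSENT1",),
        clinical=tuple(clinical),
        categories={"TOYA": "sperm motility", "TOYB": "sperm viability",
                    "TOYC": "semen viscosity"},
        ground_truth=truth,
    )


def make_toy_fixture(out_dir: str | Path) -> Tuple[Dict[str, Path], GroundTruth]:
    """Write the toy bundle to *out_dir*; see :func:`make_toy_data`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = make_toy_data()
    paths = {k: out_dir / v for k, v in BUNDLE_FILES.items()}
    write_psm_table(data.psms, paths["psm"])
    write_fasta(data.sequences, paths["fasta"])
    write_domains(data.domains, paths["domains"])
    write_marker_list(data.markers, paths["markers"], comment="toy markers")
    write_marker_list(data.exosome_markers, paths["exosome_markers"])
    write_marker_list(data.microvesicle_markers, paths["microvesicle_markers"])
    write_clinical(data.clinical, paths["clinical"])
    _write_categories(data.categories, paths["categories"])
    manifest = {
        "seed": 7, "n_psms": len(data.psms),
        "site_stoichiometry": {"TOYA:10": {"NZ": 0.4, "nonNZ": 0.2}},
    }
    with paths["manifest"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths, data.ground_truth
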
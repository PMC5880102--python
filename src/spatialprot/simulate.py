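"""Synthetic data with known ground truth for every pipeline stage.

The generator follows the additive-multiplicative error structure that the
variance-stabilizing transform in :mod:`spatialprot.preprocess` assumes: the
intensity of PSM ``p`` of protein ``i`` in channel ``j`` is

    loading_j * (alpha + A_ij * pep_factor * exp(eta) + eps)_+

with ``eta ~ N(0, sd_eta^2)`` multiplicative log-noise, ``eps ~ N(0,
sd_eps^2)`` additive noise and negatives clipped to zero.  Intensity-floor
censoring is *not* applied here; filtering is the pipeline's job.

All noise magnitudes are synthetic defaults chosen for testability; they are
not estimates from any real TMT data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import AnnotationSet, DesignTable, PsmTable, QpcrTable


class ConfigError(ValueError):
    """Simulation configuration is degenerate or inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic TMT experiment.

    ``null_sd`` is the per-channel biological null log2 variation; a centered
    two-sample ratio therefore has null sd ``sqrt(2) * null_sd`` (plus a small
    peptide-sampling contribution).
    """

    n_proteins: int = 1000
    n_patients: int = 5
    regions: tuple[str, ...] = ("tumor", "peritumor")
    # peptides per protein: 1 + Geometric(p), truncated at peptides_max
    peptides_geom_p: float = 0.25
    peptides_max: int = 30
    peptides_min: int = 1
    pi1: float = 0.1
    effect_mean: float = 1.5
    effect_sd: float = 0.3
    null_sd: float = 0.35
    # per-protein patient signature (log2), shared by all sectors of a
    # patient: makes within-patient samples more alike than cross-patient ones
    patient_sd: float = 0.3
    # base protein abundances: lognormal on log2 scale
    abundance_log2_mean: float = 15.0
    abundance_log2_sd: float = 2.0
    channel_loadings: tuple[float, ...] | None = None
    sd_eta: float = 0.2
    sd_eps: float = 50.0
    baseline_offset: float = 0.0
    peptide_efficiency_log2_sd: float = 1.0
    floor: float = 1000.0
    frac_contaminant: float = 0.02
    frac_decoy: float = 0.02
    compartment_label: str = "mitochondrion"
    compartment_fraction: float = 0.15
    compartment_shift: float = 0.0
    gradient_fraction: float = 0.0
    gradient_profile: tuple[float, ...] | None = None
    transcript_corr: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "pi1": self.pi1,
            "frac_contaminant": self.frac_contaminant,
            "frac_decoy": self.frac_decoy,
            "compartment_fraction": self.compartment_fraction,
            "gradient_fraction": self.gradient_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name, v in (("sd_eta", self.sd_eta), ("null_sd", self.null_sd)):
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if self.patient_sd < 0:
            raise ConfigError("patient_sd must be >= 0")
        if self.sd_eps < 0 or self.floor < 0 or self.baseline_offset < 0:
            raise ConfigError("sd_eps, floor and baseline_offset must be >= 0")
        if self.pi1 == 1.0 and self.effect_sd == 0.0 and self.effect_mean == 0.0:
            raise ConfigError("pi1=1 with zero effect size is a degenerate truth")
        if self.pi1 == 1.0 and self.effect_sd == 0.0:
            raise ConfigError("pi1=1 with zero effect sd is a degenerate truth")
        if not 0 < self.peptides_geom_p <= 1:
            raise ConfigError("peptides_geom_p must be in (0, 1]")
        if abs(self.transcript_corr) > 1:
            raise ConfigError("transcript_corr must be in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each simulated experiment."""

    table: pd.DataFrame  # index protein_group; columns: is_differential,
    # true_effect, compartment, in_gradient_cluster, transcript_fc
    contrast: tuple[str, str]

    @property
    def differential(self) -> set[str]:
        return set(self.table.index[self.table["is_differential"]])


@dataclass
class SimulatedExperiment:
    psm: PsmTable
    design: DesignTable
    truth: SyntheticTruth
    annotations: AnnotationSet
    transcript_fc: dict[str, float]
    config: SimulationConfig = field(repr=False, default=None)


def _draw_peptide_counts(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    counts = cfg.peptides_min + rng.geometric(cfg.peptides_geom_p, size=cfg.n_proteins) - 1
    return np.clip(counts, cfg.peptides_min, cfg.peptides_max)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a PSM table, design, ground truth, annotations and transcript
    fold changes under ``config``.  Identical config and seed give identical
    output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    regions = list(config.regions)
    n_channels = config.n_patients * len(regions)

    proteins = np.array([f"PROT{i:05d}" for i in range(n)])
    channels = [f"ch{j:02d}" for j in range(n_channels)]
    mapping = {}
    j = 0
    for p in range(config.n_patients):
        for r in regions:
            mapping[channels[j]] = (f"P{p + 1}", r)
            j += 1
    design = DesignTable(mapping=mapping)

    loadings = (
        np.asarray(config.channel_loadings, dtype=float)
        if config.channel_loadings is not None
        else np.exp(rng.normal(0.0, 0.15, size=n_channels))
    )
    if len(loadings) != n_channels:
        raise ConfigError(
            f"channel_loadings has length {len(loadings)}, expected {n_channels}"
        )

    # --- truth ------------------------------------------------------------
    is_diff = rng.random(n) < config.pi1
    signs = rng.choice([-1.0, 1.0], size=n)
    magnitudes = rng.normal(config.effect_mean, config.effect_sd, size=n)
    magnitudes = np.where(np.abs(magnitudes) < 1e-9, 1e-9, np.abs(magnitudes))
    effects = np.where(is_diff, signs * magnitudes, 0.0)

    compartment = np.full(n, "", dtype=object)
    n_comp = int(round(config.compartment_fraction * n))
    comp_idx = rng.choice(n, size=n_comp, replace=False) if n_comp else np.array([], int)
    compartment[comp_idx] = config.compartment_label

    in_gradient = np.zeros(n, dtype=bool)
    n_grad = int(round(config.gradient_fraction * n))
    if n_grad:
        grad_idx = rng.choice(n, size=n_grad, replace=False)
        in_gradient[grad_idx] = True
    profile = (
        np.asarray(config.gradient_profile, dtype=float)
        if config.gradient_profile is not None
        else np.linspace(-1.0, 1.0, len(regions))
    )
    if len(profile) != len(regions):
        raise ConfigError("gradient_profile length must equal number of regions")

    # transcript fold changes correlated with true effects
    e = effects
    e_sd = float(np.std(e))
    if e_sd > 0:
        noise = rng.normal(0.0, 1.0, size=n)
        transcript = config.transcript_corr * (e / e_sd) + np.sqrt(
            max(0.0, 1.0 - config.transcript_corr**2)
        ) * noise
        transcript *= e_sd  # back to a log2-like scale
    else:
        transcript = rng.normal(0.0, 0.1, size=n)

    contrast = (regions[0], regions[1]) if len(regions) >= 2 else (regions[0], regions[0])
    truth_df = pd.DataFrame(
        {
            "is_differential": is_diff,
            "true_effect": effects,
            "compartment": compartment,
            "in_gradient_cluster": in_gradient,
            "transcript_fc": transcript,
        },
        index=pd.Index(proteins, name="protein_group"),
    )
    truth = SyntheticTruth(table=truth_df, contrast=contrast)

    # --- per-channel true abundances --------------------------------------
    base_log2 = rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, size=n)
    region_of = np.array([mapping[ch][1] for ch in channels])
    log2_a = np.tile(base_log2[:, None], (1, n_channels))
    is_region_a = region_of == contrast[0]
    log2_a[:, is_region_a] += effects[:, None]
    comp_mask = compartment == config.compartment_label
    if config.compartment_shift != 0.0:
        log2_a[np.ix_(comp_mask, is_region_a)] += config.compartment_shift
    if n_grad:
        sector_profile = np.array([profile[regions.index(r)] for r in region_of])
        log2_a[in_gradient, :] += sector_profile[None, :]
    # patient signature shared by all channels of a patient
    if config.patient_sd > 0:
        patient_effect = rng.normal(0.0, config.patient_sd, size=(n, config.n_patients))
        patient_idx = np.array(
            [int(mapping[ch][0][1:]) - 1 for ch in channels]
        )
        log2_a += patient_effect[:, patient_idx]
    # biological null variation per protein x channel
    log2_a += rng.normal(0.0, config.null_sd, size=(n, n_channels))
    abundance = 2.0**log2_a

    # --- peptide-level sampling -------------------------------------------
    pep_counts = _draw_peptide_counts(rng, config)
    prot_idx = np.repeat(np.arange(n), pep_counts)
    n_psm = len(prot_idx)
    pep_eff = 2.0 ** rng.normal(0.0, config.peptide_efficiency_log2_sd, size=n_psm)
    eta = rng.normal(0.0, config.sd_eta, size=(n_psm, n_channels))
    eps = rng.normal(0.0, config.sd_eps, size=(n_psm, n_channels))
    signal = abundance[prot_idx] * pep_eff[:, None] * np.exp(eta)
    inten = loadings[None, :] * np.clip(config.baseline_offset + signal + eps, 0.0, None)

    pep_ids = []
    counter: dict[int, int] = {}
    for pi in prot_idx:
        k = counter.get(pi, 0)
        counter[pi] = k + 1
        pep_ids.append(f"PEP{pi:05d}_{k:02d}")

    meta = pd.DataFrame(
        {
            "peptide_id": pep_ids,
            "protein_group": proteins[prot_idx],
            "proteotypic": True,
            "is_contaminant": False,
            "is_decoy": False,
        }
    )
    inten_df = pd.DataFrame(inten, columns=channels)

    # contaminant / decoy rows
    n_cont = int(round(config.frac_contaminant * n_psm))
    n_dec = int(round(config.frac_decoy * n_psm))
    extra_meta, extra_inten = [], []
    for k in range(n_cont):
        extra_meta.append((f"PEPCONT_{k:03d}", f"CONT{k:03d}", True, True, False))
        extra_inten.append(2.0 ** rng.normal(config.abundance_log2_mean, 1.0, n_channels))
    for k in range(n_dec):
        extra_meta.append((f"PEPDEC_{k:03d}", f"DECOY{k:03d}", True, False, True))
        extra_inten.append(2.0 ** rng.normal(config.abundance_log2_mean, 1.0, n_channels))
    if extra_meta:
        extra_df = pd.DataFrame(
            extra_meta,
            columns=["peptide_id", "protein_group", "proteotypic", "is_contaminant", "is_decoy"],
        )
        meta = pd.concat([meta, extra_df], ignore_index=True)
        inten_df = pd.concat(
            [inten_df, pd.DataFrame(np.array(extra_inten), columns=channels)],
            ignore_index=True,
        )

    psm = PsmTable(df=pd.concat([meta, inten_df], axis=1), channels=channels)

    annotations = AnnotationSet(
        compartment={p: c for p, c in zip(proteins, compartment) if c}
    )
    transcript_fc = {p: float(t) for p, t in zip(proteins, transcript)}
    return SimulatedExperiment(
        psm=psm,
        design=design,
        truth=truth,
        annotations=annotations,
        transcript_fc=transcript_fc,
        config=config,
    )


def simulate_ratios(
    n: int,
    pi1: float,
    effect_mean: float,
    effect_sd: float,
    null_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw centered log2 ratios directly on the contrast scale.

    Returns ``(z, is_differential)`` where nulls are ``N(0, null_sd^2)`` and
    alternatives additionally carry a random-sign ``N(effect_mean,
    effect_sd^2)`` magnitude.  This is the protein-level shortcut used by the
    statistical calibration checks; :func:`simulate_experiment` exercises the
    full peptide-level path.
    """
    if not 0 <= pi1 <= 1:
        raise ConfigError("pi1 must be in [0, 1]")
    if null_sd <= 0:
        raise ConfigError("null_sd must be > 0")
    rng = np.random.default_rng(seed)
    is_diff = rng.random(n) < pi1
    signs = rng.choice([-1.0, 1.0], size=n)
    mags = np.abs(rng.normal(effect_mean, effect_sd, size=n))
    z = rng.normal(0.0, null_sd, size=n) + np.where(is_diff, signs * mags, 0.0)
    return z, is_diff


DEFAULT_QPCR_TARGETS = ("MT-RNR1", "MT-TL1")
DEFAULT_QPCR_REFERENCE = "B2M"


def simulate_qpcr(
    n_samples: int,
    true_log2_mt_ratio,
    ct_noise_sd: float,
    seed: int,
    n_replicates: int = 2,
    targets: tuple[str, ...] = DEFAULT_QPCR_TARGETS,
    reference: str = DEFAULT_QPCR_REFERENCE,
) -> tuple[QpcrTable, list[tuple[str, str]]]:
    """Simulate Ct tables for paired tumor/peritumor samples.

    ``true_log2_mt_ratio`` is a scalar or per-pair array of the true log2
    mtDNA fold change (tumor vs peritumor).  With ``ct_noise_sd = 0`` the
    downstream delta-delta-Ct analysis recovers it exactly.  Returns the table
    and the (tumor, peritumor) sample pairs.
    """
    if ct_noise_sd < 0:
        raise ConfigError("ct_noise_sd must be >= 0")
    ratios = np.broadcast_to(np.asarray(true_log2_mt_ratio, dtype=float), (n_samples,))
    rng = np.random.default_rng(seed)
    rows = []
    pairs = []
    ref_ct, target_base = 20.0, 18.0
    for s in range(n_samples):
        tum, per = f"S{s + 1}_T", f"S{s + 1}_P"
        pairs.append((tum, per))
        for sample, shift in ((tum, -ratios[s]), (per, 0.0)):
            gene_bases = [(reference, ref_ct)]
            gene_bases += [(t, target_base + shift) for t in targets]
            for gene, base in gene_bases:
                for _ in range(n_replicates):
                    ct = base + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append((sample, gene, ct))
    df = pd.DataFrame(rows, columns=["sample", "gene", "ct"])
    return QpcrTable(df=df), pairs


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("regions", "channel_loadings", "gradient_profile"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
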
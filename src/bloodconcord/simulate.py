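"""Synthetic two-color microarray experiments with known structure.

The generator emulates a blood-collection platform comparison: eight donors
sampled on three preservation platforms with 3/2/3 technical replicates
(64 arrays), each array measuring the same probes against a common
reference channel.  Every downstream statistic therefore has a known
ground truth.

Generative model (log2 scale)
-----------------------------
For probe p on sample s (donor d, platform q):

    M[p, s] = mu_p + alpha_q * beta[p, d] + delta[p, q] + eps[p, s]
    eps ~ Normal(0, sigma[p, q]),
    sigma[p, q] = sigma_q * (1 + kappa_q * z(GC_p)),  floored at 0.1 * sigma_q

where ``mu_p`` is the probe baseline (test vs reference), ``beta`` are
donor effects with sd ``tau`` attenuated per-platform by ``alpha_q`` in
[0, 1], ``delta`` are probe-specific platform offsets, and ``kappa_q``
links replicate noise to probe GC content (standardized, ``z``) the way
degradation-prone chemistry would.  Channel intensities add an
intensity-dependent dye bias ``b(A)`` that within-array loess
normalization is expected to remove:

    R = 2 ** (A + M/2 + b(A)),   G = 2 ** (A - M/2),
    b(A) = dye_bias_amplitude * sin((A - intensity_mean) / intensity_sd)

A fraction of probes is spotted twice per array with independent noise,
mimicking on-array duplicate probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import GroundTruth, IntensityArray, validate_annotation

PROBE_LENGTH = 60  # nt, 60-mer oligo probes


@dataclass(frozen=True)
class PlatformSpec:
    """One preservation platform's replicate count and noise profile."""

    name: str
    n_replicates: int
    noise_sd: float  # sigma_q, log2 units
    gc_noise_link: float = 0.0  # kappa_q, >= 0
    donor_attenuation: float = 1.0  # alpha_q in [0, 1]

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"platform {self.name}: n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError(f"platform {self.name}: noise_sd must be >= 0")
        if self.gc_noise_link < 0:
            raise ValueError(f"platform {self.name}: gc_noise_link must be >= 0")
        if not 0.0 <= self.donor_attenuation <= 1.0:
            raise ValueError(
                f"platform {self.name}: donor_attenuation must be in [0, 1]"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic experiment.

    Defaults reproduce the study design: 8 donors, three platforms with
    3/2/3 technical replicates (64 arrays), 2000 probes.  Effect scales
    are in log2 units throughout.
    """

    n_donors: int = 8
    platform_specs: tuple[PlatformSpec, ...] = (
        PlatformSpec("RNAgard", 3, noise_sd=0.25, gc_noise_link=0.3,
                     donor_attenuation=1.0),
        PlatformSpec("PAXgene", 2, noise_sd=0.25, gc_noise_link=0.1,
                     donor_attenuation=0.9),
        PlatformSpec("PBMC_Trizol", 3, noise_sd=0.35, gc_noise_link=0.2,
                     donor_attenuation=0.6),
    )
    n_probes: int = 2000
    duplicate_fraction: float = 0.05
    donor_effect_sd: float = 0.25  # tau
    probe_baseline_sd: float = 1.0
    platform_offset_sd: float = 0.3
    dye_bias_amplitude: float = 0.3
    intensity_mean: float = 10.0
    intensity_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.n_probes < 1:
            raise ValueError("n_donors and n_probes must be >= 1")
        if not self.platform_specs:
            raise ValueError("at least one platform is required")
        for spec in self.platform_specs:
            spec.validate()
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        for name in ("donor_effect_sd", "probe_baseline_sd",
                     "platform_offset_sd", "intensity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_donors * sum(p.n_replicates for p in self.platform_specs)

    @property
    def platform_names(self) -> list[str]:
        return [p.name for p in self.platform_specs]

    def replace(self, **kwargs) -> "SimulationConfig":
        from dataclasses import replace

        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["platform_specs"] = [asdict(p) for p in self.platform_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["platform_specs"] = tuple(
            PlatformSpec(**p) for p in d.get("platform_specs", ())
        )
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from JSON or YAML (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # separate deterministic streams per operation, all keyed on one seed
    return np.random.default_rng([int(config.seed), stream])


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Generate per-probe physical properties.

    GC percent is uniform on [30, 70]; transcript and gene sizes are
    log-normal (genes extend transcripts by intronic sequence); the probe
    sits uniformly along the transcript, so with 0-based offsets
    ``Dist5 + Dist3 + probe_length == TranscriptSize`` exactly.  A small
    share of genes carries two probes, as on commercial designs.
    """
    rng = _rng(config, 0)
    n = config.n_probes
    probe_ids = np.array([f"P{i:06d}" for i in range(n)])

    # ~10% of probes share a gene with another probe
    n_genes = max(1, int(np.ceil(n / 1.1)))
    gene_idx = np.concatenate([
        np.arange(n_genes),
        rng.integers(0, n_genes, size=n - n_genes),
    ])[:n]
    gene_ids = np.array([f"G{i:06d}" for i in gene_idx])

    gc = rng.uniform(30.0, 70.0, size=n)
    transcript = PROBE_LENGTH + np.round(
        rng.lognormal(mean=7.5, sigma=0.6, size=n)
    ).astype(int)
    gene = transcript + np.round(
        rng.lognormal(mean=9.0, sigma=1.0, size=n)
    ).astype(int)
    start = rng.integers(0, transcript - PROBE_LENGTH + 1)  # 0-based 5' offset
    dist5 = start
    dist3 = transcript - PROBE_LENGTH - start

    annotation = pd.DataFrame({
        "probe_id": probe_ids,
        "gene_id": gene_ids,
        "Dist3": dist3,
        "Dist5": dist5,
        "TranscriptSize": transcript,
        "GeneSize": gene,
        "GCpercent": gc,
    })
    return validate_annotation(annotation)


def _noise_sds(config: SimulationConfig, gc: np.ndarray) -> pd.DataFrame:
    """Per-probe replicate noise sd per platform, GC-linked and floored."""
    z = (gc - gc.mean()) / gc.std() if gc.std() > 0 else np.zeros_like(gc)
    cols = {}
    for spec in config.platform_specs:
        sd = spec.noise_sd * (1.0 + spec.gc_noise_link * z)
        cols[spec.name] = np.maximum(sd, 0.1 * spec.noise_sd)
    return pd.DataFrame(cols)


def simulate_experiment(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[list[IntensityArray], pd.DataFrame, GroundTruth]:
    """Generate raw two-channel arrays, a sample sheet, and the ground truth.

    Returns one :class:`IntensityArray` per sample (donor x platform x
    replicate), a sample sheet DataFrame, and the latent
    :class:`GroundTruth` used to produce them.
    """
    if len(annotation) != config.n_probes:
        raise ValueError(
            f"annotation has {len(annotation)} probes, "
            f"config expects {config.n_probes}"
        )
    rng = _rng(config, 1)
    n = config.n_probes
    probe_ids = annotation["probe_id"].to_numpy()
    gene_ids = annotation["gene_id"].to_numpy()
    gc = annotation["GCpercent"].to_numpy(dtype=float)

    donors = [f"D{d:02d}" for d in range(config.n_donors)]
    mu = rng.normal(0.0, config.probe_baseline_sd, size=n)
    beta = rng.normal(0.0, config.donor_effect_sd, size=(n, config.n_donors))
    delta = rng.normal(
        0.0, config.platform_offset_sd, size=(n, len(config.platform_specs))
    )
    sigma = _noise_sds(config, gc)

    n_dup = int(np.floor(config.duplicate_fraction * n))
    dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
    occ_idx = np.concatenate([np.arange(n), dup_idx])  # occurrence -> probe row

    arrays: list[IntensityArray] = []
    sheet_rows = []
    for qi, spec in enumerate(config.platform_specs):
        sd_occ = sigma[spec.name].to_numpy()[occ_idx]
        for di, donor in enumerate(donors):
            signal = (
                mu[occ_idx]
                + spec.donor_attenuation * beta[occ_idx, di]
                + delta[occ_idx, qi]
            )
            for rep in range(1, spec.n_replicates + 1):
                sample_id = f"{spec.name}_{donor}_R{rep}"
                eps = rng.normal(0.0, 1.0, size=occ_idx.size) * sd_occ
                m = signal + eps
                a = rng.normal(
                    config.intensity_mean, config.intensity_sd, size=occ_idx.size
                )
                bias = config.dye_bias_amplitude * np.sin(
                    (a - config.intensity_mean) / config.intensity_sd
                )
                red = 2.0 ** (a + m / 2.0 + bias)
                green = 2.0 ** (a - m / 2.0)
                arrays.append(IntensityArray(
                    sample_id=sample_id,
                    data=pd.DataFrame({
                        "probe_id": probe_ids[occ_idx],
                        "gene_id": gene_ids[occ_idx],
                        "red_signal": red,
                        "green_signal": green,
                    }),
                ))
                sheet_rows.append(
                    (sample_id, donor, spec.name, rep)
                )

    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "donor_id", "platform", "replicate_index"],
    )
    idx = pd.Index(probe_ids, name="probe_id")
    truth = GroundTruth(
        mu=pd.Series(mu, index=idx, name="mu"),
        beta=pd.DataFrame(beta, index=idx, columns=donors),
        delta=pd.DataFrame(delta, index=idx, columns=config.platform_names),
        sigma=sigma.set_index(idx),
        duplicated_probes=list(probe_ids[dup_idx]),
    )
    return arrays, sheet, truth


def ground_truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    """Serialize a GroundTruth to JSON."""
    payload = {
        "probe_ids": list(truth.mu.index),
        "mu": truth.mu.round(10).tolist(),
        "beta": {c: truth.beta[c].round(10).tolist() for c in truth.beta},
        "delta": {c: truth.delta[c].round(10).tolist() for c in truth.delta},
        "sigma": {c: truth.sigma[c].round(10).tolist() for c in truth.sigma},
        "duplicated_probes": truth.duplicated_probes,
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def ground_truth_from_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    idx = pd.Index(payload["probe_ids"], name="probe_id")
    return GroundTruth(
        mu=pd.Series(payload["mu"], index=idx, name="mu"),
        beta=pd.DataFrame(payload["beta"], index=idx),
        delta=pd.DataFrame(payload["delta"], index=idx),
        sigma=pd.DataFrame(payload["sigma"], index=idx),
        duplicated_probes=payload["duplicated_probes"],
    )
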
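"""Synthetic two-experiment microbiome + host-phenotype datasets with a
planted interaction network.

The generator emulates the design of a two-experiment dietary-intervention
study: two independent experiments, each with a control and a treatment
group of ~8 mice drawn from several birth cohorts.  A shared log-normal
baseline community of ASVs is perturbed in the treatment group (a set of
"shifted" ASVs gains a consistent log2 fold change in both experiments),
and a small number of shifted ASVs are designated *bottlenecks*: host
parameters are generated as noisy monotone functions of a bottleneck's
per-sample log abundance, so that rank correlations between the bottleneck
and its linked host parameters are planted by construction.

Because every planted effect has the same direction in both experiments and
every planted microbe-host link satisfies sign(rho) = sign(microbe shift) x
sign(induced host shift), the planted structure passes the downstream
sign-consistency, fold-change-consistency and causality filters by design,
which is what makes end-to-end recovery testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AsvCountTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "write_fixture"]

# Within-group sample-to-sample biological variation of log abundance.
# Fixed (not a config knob): it sets the scale against which effect_log2fc
# and coupling_strength are interpreted.
SAMPLE_LOG_SD = 0.5

# Log-sd of the baseline rank-abundance curve; heavy-tailed so that the
# 99.5% cumulative-abundance filter removes a non-trivial set of rare ASVs.
BASELINE_LOG_SD = 1.5

_PHYLA = [
    ("Firmicutes", 0.45),
    ("Bacteroidetes", 0.35),
    ("Proteobacteria", 0.10),
    ("Actinobacteria", 0.05),
    ("Verrucomicrobia", 0.05),
]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-network generator.

    Defaults mirror the study design the pipeline targets: 2 experiments x
    2 groups x 8 samples, ~100 ASVs, a dozen treatment-shifted ASVs with a
    1 log2-unit shift, and one bottleneck ASV driving 4 host parameters.
    """

    n_experiments: int = 2
    n_samples_per_group: int = 8
    n_asvs: int = 100
    n_host_params: int = 10
    n_shifted_asvs: int = 12
    effect_log2fc: float = 1.0
    n_bottlenecks: int = 1
    hub_link_count: int = 4
    coupling_strength: float = 0.8
    sequencing_depth: int = 50_000
    batch_sd: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_experiments", "n_samples_per_group", "n_asvs",
                     "n_host_params", "sequencing_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_shifted_asvs > self.n_asvs:
            raise ValueError("n_shifted_asvs cannot exceed n_asvs")
        if self.n_bottlenecks > self.n_shifted_asvs:
            raise ValueError("n_bottlenecks cannot exceed n_shifted_asvs")
        if self.hub_link_count > self.n_host_params:
            raise ValueError("hub_link_count cannot exceed n_host_params")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.sequencing_depth < self.n_asvs:
            raise ValueError("sequencing_depth must be at least n_asvs")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``shifted_asvs`` maps ASV id -> signed treatment direction (+1 / -1);
    ``planted_edges`` lists (microbe id, host id, sign) triples where the
    sign equals the sign of the induced microbe-host correlation.
    """

    shifted_asvs: dict[str, int] = field(default_factory=dict)
    bottleneck_ids: list[str] = field(default_factory=list)
    planted_edges: list[tuple[str, str, int]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "shifted_asvs": self.shifted_asvs,
                "bottleneck_ids": self.bottleneck_ids,
                "planted_edges": [list(e) for e in self.planted_edges],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            shifted_asvs={k: int(v) for k, v in d["shifted_asvs"].items()},
            bottleneck_ids=list(d["bottleneck_ids"]),
            planted_edges=[(m, h, int(s)) for m, h, s in d["planted_edges"]],
        )


def _make_taxonomy(asv_ids: list[str], rng: np.random.Generator) -> pd.Series:
    names = [p for p, _ in _PHYLA]
    probs = np.array([w for _, w in _PHYLA])
    phyla = rng.choice(names, size=len(asv_ids), p=probs / probs.sum())
    lineages = [f"k__Bacteria;p__{p};c__;o__;f__;g__" for p in phyla]
    return pd.Series(lineages, index=asv_ids, name="lineage")


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[AsvCountTable, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (counts, host table, metadata, ground truth).

    Counts are samples x ASVs non-negative integers summing to
    ``sequencing_depth`` per sample (multinomial).  Host parameters are
    positive reals (samples x parameters).  Metadata has one row per sample
    with columns experiment, group, cohort, timepoint.  Deterministic for a
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    asv_ids = [f"ASV{j + 1:03d}" for j in range(config.n_asvs)]
    host_ids = [f"HP{p + 1:02d}" for p in range(config.n_host_params)]
    taxonomy = _make_taxonomy(asv_ids, rng)

    # Baseline community shared across experiments: heavy-tailed
    # rank-abundance curve on the natural-log scale.
    baseline_log = rng.normal(0.0, BASELINE_LOG_SD, size=config.n_asvs)

    # Shifted ASVs are drawn from the abundant half of the community so the
    # planted signal survives the cumulative-abundance prefilter; the
    # bottlenecks are the most abundant shifted ASVs (good count resolution).
    abundant_half = np.argsort(baseline_log)[::-1][: max(config.n_asvs // 2, config.n_shifted_asvs)]
    shifted_idx = rng.choice(abundant_half, size=config.n_shifted_asvs, replace=False)
    # Alternate shift signs down the abundance ranking of the shifted set so
    # the up- and down-shifted halves carry similar total abundance.  Counts
    # are compositional: an unbalanced planted shift inflates the community
    # total and cancels itself out of every ASV's relative abundance.
    shifted_idx = shifted_idx[np.argsort(baseline_log[shifted_idx])[::-1]]
    flip = int(rng.choice([-1, 1]))
    shift_signs = np.array([flip * (1 if k % 2 == 0 else -1)
                            for k in range(config.n_shifted_asvs)])
    # Bottlenecks are mid-abundance shifted ASVs: abundant enough to be well
    # sampled, but not so dominant that their within-sample rank is frozen
    # (a rank-stable ASV becomes constant under quantile normalization and
    # its correlations are undefined).
    order = np.argsort(np.abs(baseline_log[shifted_idx]
                              - np.median(baseline_log[shifted_idx])))
    bottleneck_pos = order[: config.n_bottlenecks]
    bottleneck_idx = shifted_idx[bottleneck_pos]

    truth = GroundTruth(
        shifted_asvs={asv_ids[j]: int(s) for j, s in zip(shifted_idx, shift_signs)},
        bottleneck_ids=[asv_ids[j] for j in bottleneck_idx],
    )

    delta = np.zeros(config.n_asvs)
    delta[shifted_idx] = shift_signs * config.effect_log2fc * np.log(2.0)

    # Host linkage plan: each bottleneck drives hub_link_count host
    # parameters (round-robin over the host panel), with a random link sign.
    link_sign = np.zeros((config.n_bottlenecks, config.n_host_params), dtype=int)
    p = 0
    for b in range(config.n_bottlenecks):
        for _ in range(config.hub_link_count):
            link_sign[b, p % config.n_host_params] = int(rng.choice([-1, 1]))
            p += 1
    for b, bj in enumerate(bottleneck_idx):
        m_sign = int(np.sign(delta[bj]))
        for hp in range(config.n_host_params):
            if link_sign[b, hp] != 0:
                # correlation sign = link sign; host induced direction =
                # link sign x microbe direction, so sign(rho) =
                # sign(microbe) x sign(host) holds by construction.
                truth.planted_edges.append((asv_ids[bj], host_ids[hp], int(link_sign[b, hp])))
                assert link_sign[b, hp] == m_sign * (link_sign[b, hp] * m_sign)

    host_base_scale = 10.0 * np.exp(rng.normal(0.0, 0.5, size=config.n_host_params))

    rows_counts: list[np.ndarray] = []
    rows_host: list[np.ndarray] = []
    meta_rows: list[dict] = []
    sample_index: list[str] = []

    for e in range(config.n_experiments):
        exp_label = f"Exp{e + 1}"
        n_cohorts = 3 if e % 2 == 0 else 4  # three or four birth cohorts
        asv_batch = rng.normal(0.0, config.batch_sd, size=config.n_asvs)
        host_batch = rng.normal(0.0, config.batch_sd, size=config.n_host_params)
        cohort_offset = rng.normal(0.0, config.batch_sd / 2.0,
                                   size=(n_cohorts, config.n_host_params))

        n_exp = 2 * config.n_samples_per_group
        # latent per-sample log abundances (pre-sequencing)
        eps = rng.normal(0.0, SAMPLE_LOG_SD, size=(n_exp, config.n_asvs))
        groups = (["Control"] * config.n_samples_per_group
                  + ["Treatment"] * config.n_samples_per_group)
        log_abund = baseline_log[None, :] + asv_batch[None, :] + eps
        treat_mask = np.array([g == "Treatment" for g in groups])
        log_abund[treat_mask] += delta[None, :]

        rel = np.exp(log_abund)
        rel /= rel.sum(axis=1, keepdims=True)
        counts = np.vstack([
            rng.multinomial(config.sequencing_depth, rel[i]) for i in range(n_exp)
        ])

        # host parameters: monotone (exp) functions of the bottleneck's
        # standardized observed log abundance, plus noise and cohort offsets.
        # Linking to the count-based abundance (rather than the latent one)
        # means the planted rank correlation is exact on the data a user
        # actually sees: coupling 1 with zero noise gives |rho| = 1.
        lin = rng.normal(0.0, 1.0, size=(n_exp, config.n_host_params)) * config.noise_sd
        for b, bj in enumerate(bottleneck_idx):
            x = np.log1p(counts[:, bj].astype(float))
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            lin += config.coupling_strength * np.outer(z, link_sign[b])

        cohorts = [f"{exp_label}-C{(i % n_cohorts) + 1}" for i in range(n_exp)]
        cohort_ids = np.array([i % n_cohorts for i in range(n_exp)])
        lin += cohort_offset[cohort_ids] + host_batch[None, :]
        host_vals = host_base_scale[None, :] * np.exp(lin)

        for i in range(n_exp):
            sid = f"{exp_label}-{groups[i][0]}{(i % config.n_samples_per_group) + 1:02d}"
            sample_index.append(sid)
            meta_rows.append({
                "sample_id": sid,
                "experiment": exp_label,
                "group": groups[i],
                "cohort": cohorts[i],
                "timepoint": "12wk",
            })
        rows_counts.append(counts)
        rows_host.append(host_vals)

    counts_df = pd.DataFrame(np.vstack(rows_counts), index=sample_index,
                             columns=asv_ids).astype(np.int64)
    host_df = pd.DataFrame(np.vstack(rows_host), index=sample_index, columns=host_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    return AsvCountTable(counts_df, taxonomy), host_df, metadata, truth


def write_fixture(
    dataset: tuple[AsvCountTable, pd.DataFrame, pd.DataFrame, GroundTruth],
    directory: str | Path,
) -> dict[str, Path]:
    """Write a generated dataset as the pipeline's on-disk input formats.

    Produces counts.tsv (ASV rows x sample columns), host.csv, metadata.csv,
    taxonomy.tsv and truth.json; the tables round-trip losslessly through
    :mod:`tknet.io` readers.
    """
    counts, host, metadata, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    paths = {
        "counts": directory / "counts.tsv",
        "host": directory / "host.csv",
        "metadata": directory / "metadata.csv",
        "taxonomy": directory / "taxonomy.tsv",
        "truth": directory / "truth.json",
    }
    # ASVs as rows, samples as columns: the common amplicon export layout.
    counts.counts.T.to_csv(paths["counts"], sep="\t", index_label="asv_id")
    host.to_csv(paths["host"], index_label="sample_id")
    metadata.to_csv(paths["metadata"], index_label="sample_id")
    counts.taxonomy.to_frame().to_csv(paths["taxonomy"], sep="\t", index_label="asv_id")
    paths["truth"].write_text(truth.to_json())
    return paths
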
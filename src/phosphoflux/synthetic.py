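"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make every downstream stage testable without any download:

* :func:`generate_silac_table` emulates a quantified SILAC phosphosite table
  from a four-replicate heavy/light comparison (heavy = high Cyclin A): a
  fraction of sites carry the minimal Cdk1 consensus (P at +1), a fraction
  of those carry a true log2 effect, a global additive shift emulates a
  mixing error, and replicate noise is Gaussian in log2 space with
  missing-completely-at-random dropouts.  Ground-truth ``is_spiked`` labels
  are emitted alongside but never consumed by the pipeline.
* :func:`generate_fdapa_traces` emulates photoactivation time courses as a
  two-population exponential decay (fast non-k-MT, slow k-MT fraction) on
  top of a background level, multiplied by an exponential photobleaching
  envelope, sampled every 15 s over 4 min by default.
* :func:`generate_toy_network` plants dense clusters in a sparse background
  graph for the cluster-recovery tests.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
fixed seed gives byte-identical outputs across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fdapa import FluorescenceTrace

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

__all__ = [
    "SilacSimConfig",
    "FdapaSimConfig",
    "generate_silac_table",
    "generate_fdapa_traces",
    "generate_toy_network",
]


@dataclass
class SilacSimConfig:
    """Design of a simulated SILAC phosphosite experiment.

    Defaults mirror the four-replicate high-vs-low Cyclin A design: most
    sites are null, a subset of Cdk1-motif sites carries a true ~three-fold
    (1.5 log2 units) enrichment in the heavy channel, replicate noise of
    0.3 log2 units, a mixing error of +0.2 log2 units, and 5% missing
    measurements.
    """

    n_sites: int = 2000
    n_replicates: int = 4
    frac_cdk1_motif: float = 0.4
    frac_spiked: float = 0.1
    effect_log2: float = 1.5
    replicate_sd: float = 0.3
    mixing_shift: float = 0.2
    missing_rate: float = 0.05
    protein_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_cdk1_motif", "frac_spiked", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_sites < 0:
            raise ConfigurationError(f"n_sites must be >= 0, got {self.n_sites}")
        if self.n_replicates < 2:
            raise ConfigurationError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if self.replicate_sd <= 0:
            raise ConfigurationError(f"replicate_sd must be > 0, got {self.replicate_sd}")
        if self.protein_sd < 0:
            raise ConfigurationError(f"protein_sd must be >= 0, got {self.protein_sd}")


@dataclass
class FdapaSimConfig:
    """Design of a simulated photoactivation experiment.

    Defaults describe a prometaphase-like spindle: 70% fast non-k-MT signal
    with ~15 s half-life, a slow k-MT population with ~4 min half-life,
    frames every 15 s for 4 min.
    """

    a_fast: float = 0.7
    t_half_fast: float = 15.0
    t_half_slow: float = 240.0
    noise_sd: float = 10.0
    background_level: float = 100.0
    bleach_rate: float = 0.001
    dt: float = 15.0
    t_max: float = 240.0
    n_cells: int = 10
    seed: int = 0
    i0: float = 1000.0
    condition: str = "control"
    phase: str = "prometaphase"

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_fast <= 1.0:
            raise ConfigurationError(f"a_fast must be in [0, 1], got {self.a_fast}")
        if self.t_half_fast >= self.t_half_slow:
            raise ConfigurationError(
                f"t_half_fast ({self.t_half_fast}) must be < t_half_slow ({self.t_half_slow})"
            )
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.t_max < 2 * self.dt:
            raise ConfigurationError(f"t_max must be >= 2*dt, got {self.t_max}")


def _random_window(rng: np.random.Generator, center: str, force_proline: bool) -> str:
    chars = rng.choice(AMINO_ACIDS, size=15)
    chars[7] = center
    if force_proline:
        chars[8] = "P"
    elif chars[8] == "P":  # keep non-motif sites out of the Cdk1 tier
        chars[8] = "A"
    return "".join(chars)


def generate_silac_table(cfg: SilacSimConfig) -> pd.DataFrame:
    """Simulate a quantified phosphosite table plus truth labels.

    Sites are assigned to proteins (about three sites each).  Cdk1-motif
    sites carry P at +1; a ``frac_spiked`` fraction of those carries a true
    mean log2 H/L of ``effect_log2``.  Every replicate measurement is the
    site's true value plus the mixing shift, an optional protein-level
    component (``protein_sd``), and Gaussian noise, and is missing with
    probability ``missing_rate``.  The ``is_spiked`` column is ground truth
    for benchmarking only; no pipeline stage reads it.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    cols = [f"log2_ratio_rep{r + 1}" for r in range(cfg.n_replicates)]
    if n == 0:
        return pd.DataFrame(
            columns=["protein_id", "gene", "position", "residue", "window", "loc_prob"]
            + cols
            + ["protein_log2_ratio", "is_spiked"]
        )

    n_proteins = max(n // 3, 1)
    protein_idx = rng.integers(0, n_proteins, size=n)
    protein_ids = np.array([f"P{i:05d}" for i in range(n_proteins)])
    protein_effect = rng.normal(0.0, cfg.protein_sd, size=n_proteins) if cfg.protein_sd > 0 else np.zeros(n_proteins)

    is_motif = rng.random(n) < cfg.frac_cdk1_motif
    is_spiked = is_motif & (rng.random(n) < cfg.frac_spiked)
    centers = rng.choice(np.array(list("SSSSTTTTY")), size=n)
    centers[is_motif] = rng.choice(np.array(list("ST")), size=int(is_motif.sum()))
    windows = [
        _random_window(rng, centers[i], bool(is_motif[i])) for i in range(n)
    ]

    true_mean = np.where(is_spiked, cfg.effect_log2, 0.0)
    base = true_mean + cfg.mixing_shift + protein_effect[protein_idx]
    ratios = base[:, None] + rng.normal(0.0, cfg.replicate_sd, size=(n, cfg.n_replicates))
    if cfg.missing_rate > 0:
        ratios[rng.random((n, cfg.n_replicates)) < cfg.missing_rate] = np.nan

    table = pd.DataFrame(
        {
            "protein_id": protein_ids[protein_idx],
            "gene": protein_ids[protein_idx],
            "position": rng.integers(8, 800, size=n),
            "residue": centers,
            "window": windows,
            "loc_prob": np.round(rng.uniform(0.75, 1.0, size=n), 4),
        }
    )
    for j, c in enumerate(cols):
        table[c] = ratios[:, j]
    # protein-level ratios are reported post-centring, hence no mixing shift
    table["protein_log2_ratio"] = protein_effect[protein_idx]
    table["is_spiked"] = is_spiked
    # duplicate positions within a protein would alias distinct sites
    table["position"] = table["position"] + table.groupby("protein_id").cumcount() * 1000
    return table


def generate_fdapa_traces(
    cfg: FdapaSimConfig,
) -> tuple[list[FluorescenceTrace], pd.DataFrame]:
    """Simulate photoactivation decay traces plus per-cell truth parameters.

    intensity(t) = bleach(t) * [background + I0 * (a_fast * e^(-k_fast t)
    + (1 - a_fast) * e^(-k_slow t))] + noise, with k = ln2 / t_half and
    bleach(t) = e^(-bleach_rate * t).  Each trace ships a paired background
    trace (bleach(t) * background + noise) and a whole-spindle bleach
    reference (bleach(t) * 2*I0 + noise), so every correction mode is
    exercisable.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.t_max + cfg.dt / 2, cfg.dt)
    k_fast = np.log(2.0) / cfg.t_half_fast
    k_slow = np.log(2.0) / cfg.t_half_slow
    bleach = np.exp(-cfg.bleach_rate * t)
    decay = cfg.a_fast * np.exp(-k_fast * t) + (1.0 - cfg.a_fast) * np.exp(-k_slow * t)

    traces = []
    truth_rows = []
    for c in range(cfg.n_cells):
        noise = lambda: rng.normal(0.0, cfg.noise_sd, size=t.size) if cfg.noise_sd > 0 else 0.0
        intensity = bleach * (cfg.background_level + cfg.i0 * decay) + noise()
        background = bleach * cfg.background_level + noise()
        bleach_ref = bleach * 2.0 * cfg.i0 + noise()
        cell_id = f"{cfg.condition}_{cfg.phase}_cell{c:03d}"
        traces.append(
            FluorescenceTrace(
                cell_id=cell_id,
                condition=cfg.condition,
                phase=cfg.phase,
                t=t,
                intensity=np.asarray(intensity, float),
                background=np.asarray(background, float),
                bleach_ref=np.asarray(bleach_ref, float),
            )
        )
        truth_rows.append(
            {
                "cell_id": cell_id,
                "a_fast": cfg.a_fast,
                "k_fast": k_fast,
                "k_slow": k_slow,
                "t_half_fast": cfg.t_half_fast,
                "t_half_slow": cfg.t_half_slow,
            }
        )
    return traces, pd.DataFrame(truth_rows)


def generate_toy_network(
    n_nodes: int,
    clusters: list,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant dense clusters in a sparse random background graph.

    Node pairs inside a planted cluster are connected with probability
    ``p_in``, all other pairs with ``p_out``; weights are uniform on
    [0.5, 1.0] so no edge is vanishingly light.  Returns a 3-column edge
    DataFrame (node_a, node_b, weight).  Node labels are ``N000`` ... ;
    cluster entries may be node indices or labels.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ConfigurationError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    rng = np.random.default_rng(seed)
    labels = [f"N{i:03d}" for i in range(n_nodes)]

    def as_label(x):
        return labels[x] if isinstance(x, (int, np.integer)) else str(x)

    planted = [frozenset(as_label(m) for m in c) for c in clusters]
    for c in planted:
        unknown = c - set(labels)
        if unknown:
            raise ConfigurationError(f"cluster members {sorted(unknown)} not among nodes")

    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            a, b = labels[i], labels[j]
            inside = any(a in c and b in c for c in planted)
            if rng.random() < (p_in if inside else p_out):
                rows.append((a, b, round(float(rng.uniform(0.5, 1.0)), 4)))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
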
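"""Synthetic data with the statistical structure the analysis assumes.

Generates phase-structured negative-binomial count matrices, synchronization-
enriched libraries of configurable purity, ploidy-sorted bulk profiles,
PlaCCI-like three-channel nucleus tracks with control and ablated regimes, and
fluorescence assay tables. Every generator returns ground truth sufficient to
score the downstream stage without re-simulation.

The cell cycle is parameterized by a position theta in [0, 1) partitioned into
G1, S and G2/M; phase durations are log-normal (positive and right-skewed,
matching the wide observed ranges of phase lengths in root meristems). The
control G1 mean is 20 h — G1 in this region of the root is longer than the
span of a typical time lapse — while the ablated regime combines a coordinated
G1 exit about 6 h post ablation with subsequent short G1 phases (mean 2.5 h).
The mCherry channel is high in S *and* early G2, matching the reporter's
inability to distinguish the two; truth labels still separate S from G2/M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import substream
from .io import CountMatrix, NucleusTrack, PHASES

EMISSION_STATES = ("G1", "S_early_G2", "G2M_late")


@dataclass
class SimulationConfig:
    """Full generative parameterization; one root seed drives every stage."""

    n_genes: int = 2000
    n_phase_genes_per_phase: int = 60
    n_cell_types: int = 3
    n_celltype_genes_per_type: int = 20
    n_mito_genes: int = 10

    # cycle position theta in [0,1): [0, g1_end) = G1, [g1_end, s_end) = S,
    # [s_end, 1) = G2M
    g1_end: float = 0.55
    s_end: float = 0.80

    purity: float = 0.7               # enrichment purity pi per library
    amplitude_low: float = 3.0        # per-gene fold change at phase peak
    amplitude_high: float = 10.0
    celltype_multiplier: float = 5.0
    baseline_log_mean: float = -0.7   # log-normal baseline expression
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.3        # var = mu + alpha mu^2
    libsize_log_sd: float = 0.3
    mito_fraction_mean: float = 0.02

    # bulk
    bulk_depth_per_kb: float = 30.0
    bulk_noise_sd: float = 0.2        # log-normal multiplicative; 0 = noiseless

    # phase durations (hours): log-normal with the given mean and log-sd
    g1_mean_h: float = 20.0
    g1_mean_ablated_h: float = 2.5
    s_mean_h: float = 3.0
    g2m_mean_h: float = 3.5
    duration_log_sd: float = 0.5
    early_g2_fraction: float = 0.4    # leading fraction of G2M that is mCherry-high

    # ablation / coordinated exit (hours post ablation; movies start at ablation)
    ablation_time_h: float = 0.0
    exit_window_center_h: float = 6.0
    exit_window_halfwidth_h: float = 1.0

    # imaging channels
    frame_interval_h: float = 1.0 / 6.0
    channel_on: float = 100.0
    channel_off: float = 10.0
    channel_noise_sd: float = 5.0

    # intensity assays
    cmac_g1_mean: float = 2.0
    cmac_s_mean: float = 1.0
    cmac_sigma: float = 0.15
    pulse_multiplier: float = 1.4
    pulse_frame: int = 2
    pulse_n_frames: int = 5
    wound_radius_um: float = 50.0
    insitu_rho: float = -0.5
    insitu_noise_sd: float = 2.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.g1_end < self.s_end < 1):
            raise ValueError("phase boundaries must satisfy 0 < g1_end < s_end < 1")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        if self.purity <= 1 / 3:
            warnings.warn("purity <= 1/3 provides no enrichment", stacklevel=2)
        if min(self.nb_dispersion, self.duration_log_sd) < 0:
            raise ValueError("variances must be non-negative")
        if abs(self.insitu_rho) >= 1:
            raise ValueError("|insitu_rho| must be < 1")
        if not (0 < self.early_g2_fraction < 1):
            raise ValueError("early_g2_fraction must lie in (0, 1)")

    # -- derived -----------------------------------------------------------
    @property
    def phase_bounds(self) -> dict[str, tuple[float, float]]:
        return {"G1": (0.0, self.g1_end), "S": (self.g1_end, self.s_end),
                "G2M": (self.s_end, 1.0)}

    def phase_mean_hours(self, regime: str = "control") -> dict[str, float]:
        g1 = self.g1_mean_h if regime == "control" else self.g1_mean_ablated_h
        return {"G1": g1, "S": self.s_mean_h, "G2M": self.g2m_mean_h}

    def occupancy(self, regime: str = "control") -> np.ndarray:
        """Stationary phase occupancy, proportional to mean phase duration."""
        m = self.phase_mean_hours(regime)
        w = np.array([m[p] for p in PHASES])
        return w / w.sum()

    def rng(self, stage: str) -> np.random.Generator:
        return substream(self.seed, stage)


# ---------------------------------------------------------------------------
# gene programs and count matrices
# ---------------------------------------------------------------------------

def build_phase_program(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene ground truth: assigned phase (or none), amplitude, baseline.

    Phase genes, cell-type genes and mitochondrial genes are disjoint so that
    marker recovery can be scored cleanly.
    """
    npp, nct = cfg.n_phase_genes_per_phase, cfg.n_celltype_genes_per_type
    n_special = 3 * npp + cfg.n_cell_types * nct + cfg.n_mito_genes
    if n_special > cfg.n_genes:
        raise ValueError("n_genes too small for the requested special genes")
    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    mito_ids = np.array([f"MT-{i:02d}" for i in range(cfg.n_mito_genes)], dtype=object)
    gene_ids[cfg.n_genes - cfg.n_mito_genes:] = mito_ids

    phase = np.array([""] * cfg.n_genes, dtype=object)
    celltype = np.array([""] * cfg.n_genes, dtype=object)
    # deterministic blocks: phase genes first, then cell-type genes, mito last
    for i, p in enumerate(PHASES):
        phase[i * npp:(i + 1) * npp] = p
    off = 3 * npp
    for t in range(cfg.n_cell_types):
        celltype[off + t * nct:off + (t + 1) * nct] = f"type{t}"

    amplitude = np.ones(cfg.n_genes)
    is_phase = phase != ""
    amplitude[is_phase] = rng.uniform(cfg.amplitude_low, cfg.amplitude_high,
                                      is_phase.sum())
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    # mito baselines tuned so the expected mito fraction is mito_fraction_mean
    is_mito = np.char.startswith(gene_ids.astype(str), "MT-")
    non_mito_total = baseline[~is_mito].sum()
    f = cfg.mito_fraction_mean
    baseline[is_mito] *= f * non_mito_total / ((1 - f) * baseline[is_mito].sum())
    return pd.DataFrame({
        "gene_id": gene_ids, "assigned_phase": phase, "cell_type": celltype,
        "amplitude": amplitude, "baseline": baseline,
    })


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def _theta_to_phase(theta: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    phase = np.where(theta < cfg.g1_end, "G1",
                     np.where(theta < cfg.s_end, "S", "G2M"))
    return phase.astype(object)


def simulate_cycle_cells(
    cfg: SimulationConfig,
    n_cells: int,
    phase_mix: tuple[float, float, float],
    rng: np.random.Generator | None = None,
    program: pd.DataFrame | None = None,
    library: str = "control",
    cell_prefix: str = "cell",
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw cycling cells with NB counts structured by phase and cell type.

    Each cell gets a cycle position theta inside the phase drawn from
    ``phase_mix``; a phase gene's mean is multiplied by its amplitude in cells
    of its phase and is at baseline elsewhere. Returns (counts, metadata with
    ``true_phase``, per-gene truth program).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    mix = np.asarray(phase_mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 1) > 1e-9:
        raise ValueError("phase_mix must be non-negative and sum to 1")
    rng = cfg.rng("cycle_cells") if rng is None else rng
    program = build_phase_program(cfg, rng) if program is None else program

    phase_idx = rng.choice(3, size=n_cells, p=mix)
    bounds = [cfg.phase_bounds[p] for p in PHASES]
    lo = np.array([b[0] for b in bounds])[phase_idx]
    hi = np.array([b[1] for b in bounds])[phase_idx]
    theta = rng.uniform(lo, hi)
    true_phase = np.array(PHASES, dtype=object)[phase_idx]
    cell_type = np.array([f"type{t}" for t in rng.integers(cfg.n_cell_types, size=n_cells)],
                         dtype=object)
    size_factor = rng.lognormal(0.0, cfg.libsize_log_sd, n_cells)

    base = program["baseline"].to_numpy()[:, None] * np.ones((1, n_cells))
    gene_phase = program["assigned_phase"].to_numpy()
    amp = program["amplitude"].to_numpy()
    for p in PHASES:
        g = gene_phase == p
        c = true_phase == p
        base[np.ix_(g, c)] *= amp[g][:, None]
    gene_ct = program["cell_type"].to_numpy()
    for t in range(cfg.n_cell_types):
        g = gene_ct == f"type{t}"
        c = cell_type == f"type{t}"
        base[np.ix_(g, c)] *= cfg.celltype_multiplier
    mu = base * size_factor[None, :]

    counts = _nb_counts(mu, cfg.nb_dispersion, rng)
    cell_ids = np.array([f"{cell_prefix}{i:05d}" for i in range(n_cells)], dtype=object)
    cm = CountMatrix(sp.csr_matrix(counts), program["gene_id"].to_numpy(), cell_ids)
    meta = pd.DataFrame({
        "cell_id": cell_ids, "library": library, "cell_type": cell_type,
        "true_phase": true_phase, "theta": theta,
    })
    return cm, meta, program


def simulate_synchronized_libraries(
    cfg: SimulationConfig, cells_per_library: int,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Four libraries: control plus one enriched library per phase.

    In the library enriched for phase p a fraction ``purity`` of cells is truly
    in p; the remainder follows the control occupancy restricted to the other
    phases. The control library follows duration-weighted occupancy (longer
    phases hold more cells).
    """
    rng = cfg.rng("synchronized_libraries")
    program = build_phase_program(cfg, rng)
    occ = cfg.occupancy()
    blocks, metas = [], []
    specs = [("control", None)] + [(f"{p}_enriched", p) for p in PHASES]
    for lib, target in specs:
        if target is None:
            mix = occ
        else:
            mix = occ.copy()
            ti = PHASES.index(target)
            rest = np.delete(occ, ti)
            mix = np.insert(rest / rest.sum() * (1 - cfg.purity), ti, cfg.purity)
        cm, meta, _ = simulate_cycle_cells(
            cfg, cells_per_library, tuple(mix), rng=rng, program=program,
            library=lib, cell_prefix=f"{lib}_",
        )
        blocks.append(cm.counts)
        metas.append(meta)
    counts = sp.hstack(blocks, format="csr")
    meta = pd.concat(metas, ignore_index=True)
    cm = CountMatrix(counts, program["gene_id"].to_numpy(),
                     meta["cell_id"].to_numpy())
    return cm, meta, program


def simulate_ploidy_bulk(
    cfg: SimulationConfig, replicates: int = 2,
    program: pd.DataFrame | None = None,
):
    """Bulk profiles of ploidy-sorted pools: one sample per phase per sort.

    Two independent sorts of three ploidy pools give six samples by default.
    Sample counts scatter log-normally around phase-mean expression scaled by
    gene length; ``bulk_noise_sd = 0`` gives identical within-phase replicates.
    """
    from .bulk import BulkTable

    if replicates < 2:
        raise ValueError("replicates must be >= 2 (independent sorts)")
    rng = cfg.rng("ploidy_bulk")
    program = build_phase_program(cfg, rng) if program is None else program
    lengths = rng.integers(500, 3000, size=len(program)).astype(float)

    expr = np.tile(program["baseline"].to_numpy()[:, None], (1, 3))
    gene_phase = program["assigned_phase"].to_numpy()
    amp = program["amplitude"].to_numpy()
    for j, p in enumerate(PHASES):
        g = gene_phase == p
        expr[g, j] *= amp[g]

    samples, phases_of = [], []
    counts = np.zeros((len(program), 3 * replicates))
    for r in range(replicates):
        for j, p in enumerate(PHASES):
            k = r * 3 + j
            mean = expr[:, j] * (lengths / 1000.0) * cfg.bulk_depth_per_kb
            noise = (rng.lognormal(0.0, cfg.bulk_noise_sd, len(program))
                     if cfg.bulk_noise_sd > 0 else 1.0)
            counts[:, k] = np.round(mean * noise)
            samples.append(f"{p}_sort{r + 1}")
            phases_of.append(p)
    table = BulkTable(
        counts=pd.DataFrame(counts.astype(np.int64),
                            index=program["gene_id"].to_numpy(), columns=samples),
        gene_lengths=pd.Series(lengths, index=program["gene_id"].to_numpy()),
        sample_phase=pd.Series(phases_of, index=samples),
    )
    return table, program


# ---------------------------------------------------------------------------
# PlaCCI tracks
# ---------------------------------------------------------------------------

def _draw_duration(cfg: SimulationConfig, phase: str, regime: str,
                   rng: np.random.Generator) -> float:
    mean = cfg.phase_mean_hours(regime)[phase]
    sigma = cfg.duration_log_sd
    mu = np.log(mean) - sigma ** 2 / 2
    return float(rng.lognormal(mu, sigma))


def _phase_timeline(cfg: SimulationConfig, regime: str, movie_hours: float,
                    rng: np.random.Generator) -> list[tuple[str, float, float]]:
    """Semi-Markov G1 -> S -> G2M -> (division) -> G1 segment list.

    Covers [0, movie_hours]; segments are (phase, start, end) in hours, with
    start of the first segment possibly negative (phase underway at t = 0).
    The initial state is approximately stationary: phase drawn proportional to
    its mean duration, with a uniform elapsed fraction.
    """
    occ = cfg.occupancy("control")  # pre-movie history is unablated
    p0 = int(rng.choice(3, p=occ))
    phase = PHASES[p0]
    d0 = _draw_duration(cfg, phase, "control", rng)
    start = -rng.uniform(0, d0)
    segments = []
    t, cur, dur = start, phase, d0
    post_ablation = False
    while t < movie_hours:
        end = t + dur
        if (regime == "ablated" and cur == "G1" and not post_ablation
                and t <= cfg.ablation_time_h < end):
            # coordinated exit: cells in G1 at ablation leave G1 together
            lo = cfg.ablation_time_h + cfg.exit_window_center_h - cfg.exit_window_halfwidth_h
            hi = cfg.ablation_time_h + cfg.exit_window_center_h + cfg.exit_window_halfwidth_h
            end = float(rng.uniform(lo, hi))
        if regime == "ablated" and end > cfg.ablation_time_h:
            post_ablation = True
        segments.append((cur, t, end))
        t = end
        cur = PHASES[(PHASES.index(cur) + 1) % 3]
        dur = _draw_duration(cfg, cur,
                             "ablated" if (regime == "ablated" and post_ablation) else "control",
                             rng)
    return segments


def _emission_segments(cfg: SimulationConfig,
                       segments: list[tuple[str, float, float]]) -> pd.DataFrame:
    """Split G2M segments into mCherry-high early G2 and YFP-high late G2/M."""
    rows = []
    for phase, s, e in segments:
        if phase == "G2M":
            split = s + cfg.early_g2_fraction * (e - s)
            rows.append(("S_early_G2", phase, s, split))
            rows.append(("G2M_late", phase, split, e))
        else:
            state = "G1" if phase == "G1" else "S_early_G2"
            rows.append((state, phase, s, e))
    return pd.DataFrame(rows, columns=["emission_state", "true_phase", "start_h", "end_h"])


def simulate_placci_tracks(
    cfg: SimulationConfig, n_tracks: int, regime: str = "control",
    movie_hours: float = 15.0,
) -> list[NucleusTrack]:
    """Three-channel nucleus tracks with a retained truth timeline.

    CFP is high in G1, mCherry in S and early G2, YFP in late G2/M, each with
    additive Gaussian noise. In the ablated regime movies start at the
    ablation; cells in G1 then exit together about 6 h later and subsequent G1
    phases are short. ``track.truth`` holds the continuous emission segments.
    """
    if movie_hours <= 0:
        raise ValueError("movie_hours must be positive")
    if regime not in ("control", "ablated"):
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "ablated":
        w_end = cfg.ablation_time_h + cfg.exit_window_center_h + cfg.exit_window_halfwidth_h
        if w_end > movie_hours:
            warnings.warn("coordinated-exit window extends beyond the movie span",
                          stacklevel=2)
    rng = cfg.rng(f"placci_tracks_{regime}")
    times = np.arange(0.0, movie_hours + 1e-9, cfg.frame_interval_h)
    tracks = []
    for i in range(n_tracks):
        segs = _phase_timeline(cfg, regime, movie_hours, rng)
        em = _emission_segments(cfg, segs)
        state = np.empty(len(times), dtype=object)
        for _, row in em.iterrows():
            mask = (times >= row.start_h) & (times < row.end_h)
            state[mask] = row.emission_state
        state[state == None] = em["emission_state"].iloc[-1]  # noqa: E711 (last frame edge)
        chans = {}
        for ch, on_state in (("cfp", "G1"), ("mcherry", "S_early_G2"),
                             ("yfp", "G2M_late")):
            level = np.where(state == on_state, cfg.channel_on, cfg.channel_off)
            chans[ch] = level + rng.normal(0, cfg.channel_noise_sd, len(times))
        truth = em.copy()
        truth["track_id"] = f"{regime}_{i:04d}"
        tracks.append(NucleusTrack(
            track_id=f"{regime}_{i:04d}",
            cell_file=f"file{i % 4}",
            time_h=times,
            cfp=chans["cfp"], mcherry=chans["mcherry"], yfp=chans["yfp"],
            x=np.full(len(times), float(rng.uniform(0, 100))),
            y=np.full(len(times), float(rng.uniform(0, 100))),
            ablation_time_h=cfg.ablation_time_h if regime == "ablated" else None,
            truth=truth,
        ))
    return tracks


# ---------------------------------------------------------------------------
# intensity assays
# ---------------------------------------------------------------------------

def simulate_intensity_assay(cfg: SimulationConfig, n_nuclei: int,
                             mode: str = "cmac_phase") -> pd.DataFrame:
    """Fluorescence assay tables for the CMAC / in situ quantifications.

    ``cmac_phase``: per-nucleus intensity with a phase-dependent mean (G1 above
    S, emulating higher nuclear glutathione in G1). ``cmac_ablation_pulse``:
    per-nucleus time series with a transient multiplicative pulse at the pulse
    frame for nuclei inside the wound radius. ``insitu_pair``: bivariate
    per-cell probe signals with correlation ``insitu_rho``.
    """
    rng = cfg.rng(f"intensity_{mode}")
    if mode == "cmac_phase":
        phase = np.where(np.arange(n_nuclei) % 2 == 0, "G1", "S").astype(object)
        mean = np.where(phase == "G1", cfg.cmac_g1_mean, cfg.cmac_s_mean)
        return pd.DataFrame({
            "nucleus_id": [f"n{i:04d}" for i in range(n_nuclei)],
            "cell_file": [f"file{i % 4}" for i in range(n_nuclei)],
            "phase": phase,
            "intensity": mean + rng.normal(0, cfg.cmac_sigma, n_nuclei),
        })
    if mode == "cmac_ablation_pulse":
        dist = rng.uniform(0, 2 * cfg.wound_radius_um, n_nuclei)
        rows = []
        for i in range(n_nuclei):
            base = rng.lognormal(0.0, 0.1)
            for f in range(cfg.pulse_n_frames):
                v = base * rng.lognormal(0.0, 0.05)
                if f == cfg.pulse_frame and dist[i] <= cfg.wound_radius_um:
                    v *= cfg.pulse_multiplier
                rows.append({"nucleus_id": f"n{i:04d}", "frame": f,
                             "intensity": v, "wound_distance_um": dist[i]})
        return pd.DataFrame(rows)
    if mode == "insitu_pair":
        cov = np.array([[1.0, cfg.insitu_rho], [cfg.insitu_rho, 1.0]])
        z = rng.multivariate_normal([0, 0], cov, size=n_nuclei)
        return pd.DataFrame({
            "cell_id": [f"c{i:04d}" for i in range(n_nuclei)],
            "probe_a": 10 + cfg.insitu_noise_sd * z[:, 0],
            "probe_b": 10 + cfg.insitu_noise_sd * z[:, 1],
        })
    raise ValueError(f"unknown mode {mode!r}")
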
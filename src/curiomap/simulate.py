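"""Synthetic study generator: rooms, agents, ratings, traits, sketch scores.

Two generators cover complementary needs:

* :func:`generate_cohort` — a full agent-based dataset.  Each trial is a
  correlated random walk through an occluded room at fixed speed (3.4 m/s,
  60 Hz).  A latent trial-level *curiosity drive* raises the walker's
  revisit-avoidance and lowers its home pull and pausing, so higher drive
  yields broader spatial coverage (higher path roaming entropy); a latent
  *interest* level widens head-direction scanning.  Discretised 1-10 ratings
  track the latents, trait Stress Tolerance moderates the drive-coverage
  coupling, and two-rater sketch scores are generated from the curiosity
  latent and realised path coverage.

* :func:`generate_linear_cohort` — outcomes drawn *exactly* from the
  multilevel regression structure that the model stage fits, with every
  coefficient recorded as ground truth.  Used for quantitative parameter
  recovery, interval-coverage and mediation checks, where the agent model has
  no analytic ground-truth coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .entropy import bin_path, roaming_entropy
from .rooms import RoomGrid, generate_room

__all__ = [
    "SimConfig",
    "LinearEffects",
    "Cohort",
    "simulate_trajectory",
    "generate_cohort",
    "generate_linear_cohort",
    "ROOM_LABELS",
]

ROOM_LABELS = [
    "Museum", "Library", "Lounge", "Bedroom", "Classroom", "Kitchen",
    "Office", "Cafe", "Gallery", "Studio", "Workshop", "Bookshop",
    "Cinema", "GardenRoom", "DiningRoom", "MusicRoom", "Lab", "Atrium",
]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration of the agent-based generator.

    Defaults emulate the study conditions: 60 participants exploring 16
    rooms of 16 m x 16 m at a fixed 3.4 m/s sampled at 60 Hz, log-normal
    room-visit durations with mean ~33 s and SD ~23 s, 1-10 integer ratings,
    trait subscales on [1, 7] and two-rater sketch scores on the 0.5 grid.
    """

    n_participants: int = 60
    n_rooms: int = 16
    hz: float = 60.0
    speed_mps: float = 3.4
    duration_mean_s: float = 33.0
    duration_sd_s: float = 23.0
    occlusion_fraction: float = 0.3
    # couplings between latents and behaviour
    beta_drive_coverage: float = 0.9
    beta_interest_scan: float = 0.6
    trait_moderation: float = 0.25
    map_betas: tuple[float, float] = (0.25, 1.2)  # (curiosity latent, path RE)
    # latent structure and noise
    latent_corr: float = 0.4
    person_sd: float = 0.5
    rating_noise_sd: float = 0.8
    sketch_person_sd: float = 0.35
    sketch_dim_sd: float = 0.30
    rater_noise_sd: float = 0.32
    gaze_base_sd: float = 2.5  # deg per 60 Hz step
    pitch_base_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hz <= 0 or self.speed_mps <= 0:
            raise ValueError("hz and speed_mps must be positive")
        for name in ("rating_noise_sd", "sketch_person_sd", "sketch_dim_sd",
                     "rater_noise_sd", "gaze_base_sd", "pitch_base_sd", "person_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 < self.latent_corr < 1:
            raise ValueError("latent_corr must be in (-1, 1)")


def _wrap180(a: np.ndarray | float):
    """Wrap degrees into [-180, 180)."""
    return (a + 180.0) % 360.0 - 180.0


def simulate_trajectory(
    room: RoomGrid,
    drive: float,
    scan_rate: float,
    duration_s: float,
    cfg: SimConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Correlated random walk with drive-dependent coverage.

    The walker starts at the room's entry cell heading into the room and moves
    ``speed_mps / hz`` per sample.  Candidate headings are weighted by
    persistence, by avoidance of already-visited cells (strength rising with
    ``beta_drive_coverage * drive``) and by a pull toward the entry that
    weakens with drive; pausing probability also falls with drive.  Gaze yaw
    performs a mean-reverting random walk around the movement heading whose
    innovation SD grows with ``beta_interest_scan * scan_rate``; pitch is a
    mean-reverting walk around 0.  Output columns: t, x, y (metres),
    yaw in [-180, 180) relative to the entry direction, pitch in [-90, 90].
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not (np.isfinite(drive) and np.isfinite(scan_rate)):
        raise ValueError("drive and scan_rate must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration_s * cfg.hz))
    step = cfg.speed_mps / cfg.hz
    ncell = room.n_cells_side
    cell_m = room.cell_m
    side = room.side_m
    mask = room.accessible

    entry = room.entry_cell or (0, ncell // 2)
    er, ec = entry
    x = (ec + 0.5) * cell_m
    y = (er + 0.5) * cell_m
    # head into the room, away from the nearest wall
    heading = 90.0 if er < ncell // 2 else -90.0
    entry_heading = heading

    u = cfg.beta_drive_coverage * drive
    lam = math.exp(-0.6 + u)  # revisit-avoidance strength
    eta = 0.15 * math.exp(-u)  # home pull
    p_stay = 0.35 / (1.0 + math.exp(1.4 * u))
    v = cfg.beta_interest_scan * scan_rate
    sig_yaw = cfg.gaze_base_sd * math.exp(v)
    sig_pitch = cfg.pitch_base_sd * math.exp(v)
    rho = 0.97  # mean reversion of the gaze offset

    offs = np.deg2rad(np.linspace(-100.0, 100.0, 9))
    cos_off = np.cos(offs)
    lookahead = 1.0  # metres; horizon at which candidate cells are scored

    rows_r, cols_c = np.indices(mask.shape)
    dist_entry = np.hypot(rows_r - er, cols_c - ec)
    visits = np.zeros_like(mask, dtype=np.float64)

    xs = np.empty(n)
    ys = np.empty(n)
    yaws = np.empty(n)
    pitches = np.empty(n)
    gaze = 0.0
    pitch = 0.0

    normals = rng.standard_normal((n, 2))
    uniforms = rng.random((n, 2))

    for i in range(n):
        xs[i] = x
        ys[i] = y
        yaws[i] = _wrap180(heading + gaze - entry_heading)
        pitches[i] = pitch
        row = min(int(y / cell_m), ncell - 1)
        col = min(int(x / cell_m), ncell - 1)
        visits[row, col] += 1.0

        gaze = rho * gaze + sig_yaw * normals[i, 0]
        pitch = min(90.0, max(-90.0, 0.98 * pitch + sig_pitch * normals[i, 1]))

        if uniforms[i, 0] < p_stay:
            continue

        ang = np.deg2rad(heading) + offs
        dx = np.cos(ang)
        dy = np.sin(ang)
        nx = x + step * dx
        ny = y + step * dy
        ncol = np.minimum((nx / cell_m).astype(int), ncell - 1)
        nrow = np.minimum((ny / cell_m).astype(int), ncell - 1)
        valid = (nx >= 0) & (nx <= side) & (ny >= 0) & (ny <= side)
        valid &= mask[np.clip(nrow, 0, ncell - 1), np.clip(ncol, 0, ncell - 1)]
        if not valid.any():
            heading = _wrap180(heading + 180.0)
            continue
        # score candidates at a 1 m horizon so cell-level terms can act
        lx = np.clip(x + lookahead * dx, 0.0, side)
        ly = np.clip(y + lookahead * dy, 0.0, side)
        lcol = np.minimum((lx / cell_m).astype(int), ncell - 1)
        lrow = np.minimum((ly / cell_m).astype(int), ncell - 1)
        score = 1.2 * cos_off - lam * np.log1p(visits[lrow, lcol]) - eta * dist_entry[lrow, lcol]
        score -= 4.0 * (~mask[lrow, lcol])  # discourage dead-end horizons
        score[~valid] = -np.inf
        w = np.exp(score - score[valid].max())
        w[~valid] = 0.0
        cw = np.cumsum(w)
        j = int(np.searchsorted(cw, uniforms[i, 1] * cw[-1]))
        j = min(j, len(offs) - 1)
        x = float(nx[j])
        y = float(ny[j])
        heading = _wrap180(heading + math.degrees(offs[j]))

    t = np.arange(n) / cfg.hz
    return pd.DataFrame({"t": t, "x": xs, "y": ys, "yaw": yaws, "pitch": pitches})


def _traits(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """5DCR-style subscale scores on [1, 7] (Joyous Exploration, Deprivation
    Sensitivity, Stress Tolerance, Thrill Seeking)."""
    cols = {
        "trait_JE": rng.normal(5.0, 0.8, n),
        "trait_DS": rng.normal(3.9, 0.9, n),
        "trait_ST": rng.normal(4.0, 0.9, n),
        "trait_TS": rng.normal(3.5, 1.0, n),
    }
    df = pd.DataFrame({k: np.clip(np.round(v, 2), 1.0, 7.0) for k, v in cols.items()})
    df.insert(0, "participant_id", [f"P{i + 1:03d}" for i in range(n)])
    return df


def _rating(latent: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Monotone discretisation of a latent onto the 1-10 integer scale."""
    raw = 5.5 + 1.6 * latent + rng.normal(0.0, noise_sd, size=np.shape(latent))
    return np.clip(np.round(raw), 1, 10).astype(int)


def _durations(rng: np.random.Generator, n: int, mean_s: float, sd_s: float) -> np.ndarray:
    """Log-normal room-visit durations matched to the target mean and SD."""
    cv2 = (sd_s / mean_s) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean_s) - sigma2 / 2.0
    return np.clip(rng.lognormal(mu, math.sqrt(sigma2), n), 5.0, 150.0)


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 2.0) / 2.0, 1.0, 5.0)


@dataclass
class Cohort:
    """A full synthetic dataset plus the ground-truth record behind it."""

    rooms: dict[str, RoomGrid]
    trajectories: pd.DataFrame
    ratings: pd.DataFrame
    traits: pd.DataFrame
    sketch_scores: pd.DataFrame
    latents: pd.DataFrame
    ground_truth: dict

    def write(self, outdir) -> None:
        """Serialise the dataset in the package's delimited/mask formats."""
        import json
        from pathlib import Path

        from .io import write_trajectories
        from .rooms import write_mask

        outdir = Path(outdir)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        write_trajectories(self.trajectories, outdir / "trajectories.csv")
        self.ratings.to_csv(outdir / "ratings.csv", index=False)
        self.traits.to_csv(outdir / "traits.csv", index=False)
        self.sketch_scores.to_csv(outdir / "sketch_scores.csv", index=False)
        for rid, room in self.rooms.items():
            write_mask(room, outdir / "masks" / f"{rid}.txt")
        (outdir / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=2))


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Generate the agent-based dataset described by ``cfg`` (deterministic in cfg.seed)."""
    root = np.random.SeedSequence(cfg.seed)
    s_rooms, s_people, s_trials, s_sketch = root.spawn(4)
    rng_people = np.random.default_rng(s_people)

    rooms: dict[str, RoomGrid] = {}
    room_rngs = s_rooms.spawn(cfg.n_rooms)
    for r in range(cfg.n_rooms):
        rid = f"R{r + 1:02d}"
        rooms[rid] = generate_room(
            np.random.default_rng(room_rngs[r]),
            cfg.occlusion_fraction,
            room_id=rid,
        )
    labels = {rid: ROOM_LABELS[i % len(ROOM_LABELS)] for i, rid in enumerate(rooms)}

    traits = _traits(rng_people, cfg.n_participants)
    st_centred = traits["trait_ST"] - traits["trait_ST"].mean()
    a_cur = rng_people.normal(0.0, cfg.person_sd, cfg.n_participants)
    a_int = rng_people.normal(0.0, cfg.person_sd, cfg.n_participants)
    u_sketch = rng_people.normal(0.0, cfg.sketch_person_sd, cfg.n_participants)

    cov = np.array([[1.0, cfg.latent_corr], [cfg.latent_corr, 1.0]])
    chol = np.linalg.cholesky(cov)

    trial_rngs = iter(s_trials.spawn(cfg.n_participants * cfg.n_rooms))
    rng_sketch = np.random.default_rng(s_sketch)

    traj_frames = []
    rating_rows = []
    latent_rows = []
    sketch_rows = []
    for j in range(cfg.n_participants):
        pid = traits["participant_id"].iloc[j]
        for rid, room in rooms.items():
            rng = np.random.default_rng(next(trial_rngs))
            z = chol @ rng.standard_normal(2)
            drive = a_cur[j] + z[0]
            interest = a_int[j] + z[1]
            drive_eff = drive * (1.0 + cfg.trait_moderation * st_centred.iloc[j])
            curiosity = int(_rating(np.array(drive), rng, cfg.rating_noise_sd))
            interest_rating = int(_rating(np.array(interest), rng, cfg.rating_noise_sd))
            duration = float(_durations(rng, 1, cfg.duration_mean_s, cfg.duration_sd_s)[0])
            samples = simulate_trajectory(room, drive_eff, interest, duration, cfg, rng)
            path_re = roaming_entropy(bin_path(samples, room))

            frame = samples.copy()
            frame.insert(0, "room_id", rid)
            frame.insert(0, "participant_id", pid)
            traj_frames.append(frame)
            rating_rows.append(
                {
                    "participant_id": pid, "room_id": rid, "room_label": labels[rid],
                    "curiosity": curiosity, "interest": interest_rating,
                    "duration_s": round(duration, 3),
                }
            )
            latent_rows.append(
                {
                    "participant_id": pid, "room_id": rid,
                    "curiosity_drive": drive, "interest_level": interest,
                    "drive_effective": drive_eff, "path_re": path_re,
                }
            )
            base = (
                3.0
                + cfg.map_betas[0] * drive
                + cfg.map_betas[1] * (path_re - 0.55)
                + u_sketch[j]
            )
            dims = base + rng_sketch.normal(0.0, cfg.sketch_dim_sd, 4)
            for rater in ("rater1", "rater2"):
                noisy = dims + rng_sketch.normal(0.0, cfg.rater_noise_sd, 4)
                vals = _round_half(noisy)
                sketch_rows.append(
                    {
                        "participant_id": pid, "room_id": rid, "rater_id": rater,
                        "OP": vals[0], "SD": vals[1], "RP": vals[2], "SP": vals[3],
                    }
                )

    ground_truth = asdict(cfg)
    ground_truth["kind"] = "agent"
    return Cohort(
        rooms=rooms,
        trajectories=pd.concat(traj_frames, ignore_index=True),
        ratings=pd.DataFrame(rating_rows),
        traits=traits,
        sketch_scores=pd.DataFrame(sketch_rows),
        latents=pd.DataFrame(latent_rows),
        ground_truth=ground_truth,
    )


@dataclass(frozen=True)
class LinearEffects:
    """Ground-truth coefficients of the linear-response generator.

    Within-person effects default to published-scale values for a 60 x 16
    study: curiosity raises path RE and map precision, interest raises
    head-direction RE, Stress Tolerance strengthens the curiosity-path
    coupling, and path RE carries the curiosity -> coverage -> precision
    mediation chain.  Residual SDs are sized so those effects are estimable
    at n = 60 x 16 (see docs/methods.md for the power reasoning).
    """

    # exploration model, within-person
    b_cur_path: float = 0.0039
    b_int_path: float = -0.0023
    b_cur_head: float = -0.0009
    b_int_head: float = 0.0058
    # exploration model, between-person and duration
    b_curm_path: float = 0.004
    b_intm_path: float = 0.0
    b_curm_head: float = 0.0
    b_intm_head: float = 0.004
    b_dur_path: float = 0.0015
    b_dur_head: float = 0.0005
    # trait moderation (per centred Stress-Tolerance unit, on the curiosity slope)
    theta_st: float = 0.0041
    # map model
    b_cur_map: float = 0.066
    b_int_map: float = -0.023
    b_path_map: float = 0.80
    b_head_map: float = -0.075
    b_curm_map: float = 0.04
    b_intm_map: float = 0.0
    b_pathm_map: float = 0.5
    b_headm_map: float = 2.2
    b_dur_map: float = 0.001
    # intercepts, random effects and residuals
    icpt_path: float = 0.55
    icpt_head: float = 0.45
    icpt_map: float = 3.2
    sd_u_path: float = 0.04
    sd_u_head: float = 0.03
    sd_u_map: float = 0.30
    sd_slope: float = 0.001
    sd_e_path: float = 0.05
    sd_e_head: float = 0.04
    sd_e_map: float = 0.30
    resid_corr: float = 0.34

    @classmethod
    def null(cls) -> "LinearEffects":
        """All structural effects zero (for interval-coverage checks)."""
        zeroed = {
            f: 0.0
            for f in (
                "b_cur_path", "b_int_path", "b_cur_head", "b_int_head",
                "b_curm_path", "b_intm_path", "b_curm_head", "b_intm_head",
                "b_dur_path", "b_dur_head", "theta_st",
                "b_cur_map", "b_int_map", "b_path_map", "b_head_map",
                "b_curm_map", "b_intm_map", "b_pathm_map", "b_headm_map", "b_dur_map",
            )
        }
        return cls(**zeroed)


def generate_linear_cohort(
    n_participants: int = 60,
    n_trials: int = 16,
    effects: LinearEffects | None = None,
    seed: int = 0,
) -> dict:
    """Trial table drawn exactly from the fitted multilevel structure.

    Outcomes are generated from the *realised* within-person deviations of the
    integer ratings, so the recorded coefficients are the exact ground truth
    of the models the package fits.  Returns ``{"trials", "traits",
    "ground_truth"}``; the trial table has one row per participant x room with
    ratings, duration, path/head RE and a continuous composite score.
    """
    eff = effects or LinearEffects()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    J, R = n_participants, n_trials

    traits = _traits(rng, J)
    st_c = (traits["trait_ST"] - traits["trait_ST"].mean()).to_numpy()

    a_cur = rng.normal(0.0, 0.5, J)
    a_int = rng.normal(0.0, 0.5, J)
    cov = np.array([[1.0, 0.4], [0.4, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=(J, R))
    cur = _rating(a_cur[:, None] + z[..., 0], rng, 0.8).astype(float)
    inte = _rating(a_int[:, None] + z[..., 1], rng, 0.8).astype(float)
    dur = _durations(rng, J * R, 33.0, 23.0).reshape(J, R)

    def centre(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pmean = mat.mean(axis=1, keepdims=True)
        return mat - pmean, (pmean - pmean.mean()).repeat(R, axis=1)

    cur_w, cur_m = centre(cur)
    int_w, int_m = centre(inte)
    dur_c = dur - dur.mean()

    u0p = rng.normal(0.0, eff.sd_u_path, J)[:, None]
    u0h = rng.normal(0.0, eff.sd_u_head, J)[:, None]
    s_cur = rng.normal(0.0, eff.sd_slope, J)[:, None]
    s_int = rng.normal(0.0, eff.sd_slope, J)[:, None]
    ecov = np.array(
        [
            [eff.sd_e_path ** 2, eff.resid_corr * eff.sd_e_path * eff.sd_e_head],
            [eff.resid_corr * eff.sd_e_path * eff.sd_e_head, eff.sd_e_head ** 2],
        ]
    )
    e = rng.multivariate_normal([0, 0], ecov, size=(J, R))

    slope_cur_path = eff.b_cur_path + eff.theta_st * st_c[:, None] + s_cur
    path = (
        eff.icpt_path + u0p + slope_cur_path * cur_w + eff.b_int_path * int_w
        + eff.b_curm_path * cur_m + eff.b_intm_path * int_m
        + eff.b_dur_path * dur_c + e[..., 0]
    )
    head = (
        eff.icpt_head + u0h + eff.b_cur_head * cur_w + (eff.b_int_head + s_int) * int_w
        + eff.b_curm_head * cur_m + eff.b_intm_head * int_m
        + eff.b_dur_head * dur_c + e[..., 1]
    )
    path = np.clip(path, 0.01, 0.99)
    head = np.clip(head, 0.01, 0.99)

    path_w, path_m = centre(path)
    head_w, head_m = centre(head)
    u0c = rng.normal(0.0, eff.sd_u_map, J)[:, None]
    comp = (
        eff.icpt_map + u0c
        + eff.b_cur_map * cur_w + eff.b_int_map * int_w
        + eff.b_path_map * path_w + eff.b_head_map * head_w
        + eff.b_curm_map * cur_m + eff.b_intm_map * int_m
        + eff.b_pathm_map * path_m + eff.b_headm_map * head_m
        + eff.b_dur_map * dur_c + rng.normal(0.0, eff.sd_e_map, (J, R))
    )

    pids = [f"P{j + 1:03d}" for j in range(J)]
    rids = [f"R{r + 1:02d}" for r in range(R)]
    rows = []
    for j in range(J):
        for r in range(R):
            rows.append(
                {
                    "participant_id": pids[j],
                    "room_id": rids[r],
                    "curiosity": int(cur[j, r]),
                    "interest": int(inte[j, r]),
                    "duration_s": dur[j, r],
                    "path_re": path[j, r],
                    "head_re": head[j, r],
                    "composite": comp[j, r],
                }
            )
    gt = asdict(eff)
    gt["kind"] = "linear"
    gt["indirect_effect"] = eff.b_cur_path * eff.b_path_map
    return {"trials": pd.DataFrame(rows), "traits": traits, "ground_truth": gt}
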
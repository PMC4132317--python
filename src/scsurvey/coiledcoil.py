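"""Sliding-window heptad coiled-coil propensity scanning.

The scanner follows the classic sliding-window scheme: every window of
``window`` residues is scored, for each of the 7 possible heptad
frames, as the geometric mean of per-residue propensities at the
heptad position each residue occupies in that frame.  A residue's
score is the maximum over all windows covering it and all frames, and
is converted to a coiled-coil probability from two Gaussian score
distributions (coiled-coil vs globular) with a globular prior:

    P(cc | x) = G_cc(x) / (G_cc(x) + prior_ratio * G_glob(x))

The shipped propensity table is package-constructed (synthetic):
hydrophobics enriched at the a/d core positions, charged residues at
e/g, helix breakers disfavoured.  The Gaussian score statistics were
calibrated once, reproducibly, by ``scripts/calibrate_coils.py``
against heptad-model and background-composition sequences; see
docs/methods.md for the procedure and its limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import maximum_filter1d  # noqa: F401  (kept for users; see _trailing_max)

from .seqio import ALPHABET, AMINO_ACIDS, ProteinRecord

HEPTAD = "abcdefg"

#: window-28 Gaussian statistics of max-over-frame window scores,
#: frozen from scripts/calibrate_coils.py (seed 20260924, n=4000 windows each)
GAUSS_CC_28 = (1.472, 0.157)
GAUSS_GLOB_28 = (0.829, 0.138)
PRIOR_RATIO = 30.0


def load_propensity_table(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Residue -> 7-vector of heptad-position propensities (all > 0)."""
    if path is None:
        text = resources.files("scsurvey.data").joinpath("cc_propensities.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, np.ndarray] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 8:
            raise ValueError(f"propensity row needs residue + 7 values: {line!r}")
        vals = np.array([float(v) for v in parts[1:]])
        if (vals <= 0).any():
            raise ValueError(f"propensities must be positive: {line!r}")
        table[parts[0]] = vals
    missing = [a for a in ALPHABET if a not in table]
    if missing:
        raise ValueError(f"propensity table lacks residues: {missing}")
    return table


@dataclass
class CoiledCoilParams:
    window: int = 28
    propensity: dict[str, np.ndarray] = field(default_factory=load_propensity_table)
    gauss_cc: tuple[float, float] = GAUSS_CC_28
    gauss_glob: tuple[float, float] = GAUSS_GLOB_28
    prior_ratio: float = PRIOR_RATIO

    def __post_init__(self) -> None:
        if self.window not in (14, 21, 28):
            raise ValueError("window must be one of 14, 21, 28")
        if self.gauss_cc[1] <= 0 or self.gauss_glob[1] <= 0:
            raise ValueError("Gaussian sds must be positive")
        if self.prior_ratio <= 0:
            raise ValueError("prior_ratio must be positive")


@dataclass
class CoiledCoilProfile:
    """Per-residue coiled-coil scores/probabilities plus merged segments."""

    per_residue_score: np.ndarray
    per_residue_prob: np.ndarray
    segments: list[tuple[int, int, float]] = field(default_factory=list)


def _gauss_pdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


def score_to_prob(score: np.ndarray, params: CoiledCoilParams) -> np.ndarray:
    """Two-Gaussian posterior probability; monotone in score above the
    globular mode."""
    g_cc = _gauss_pdf(score, *params.gauss_cc)
    g_gl = _gauss_pdf(score, *params.gauss_glob)
    denom = g_cc + params.prior_ratio * g_gl
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, g_cc / denom, np.where(score >= params.gauss_cc[0], 1.0, 0.0))
    return np.clip(p, 0.0, 1.0)


def _trailing_max(w: np.ndarray, width: int, n: int) -> np.ndarray:
    """For each residue i (0..n-1), max of w[s] over windows s covering i."""
    pad = np.full(width - 1, -np.inf)
    wp = np.concatenate([pad, w, pad])[: n + width - 1]
    view = np.lib.stride_tricks.sliding_window_view(wp, width)
    return view.max(axis=1)


def cc_profile(record: ProteinRecord, params: CoiledCoilParams | None = None) -> CoiledCoilProfile:
    """Scan one sequence; see module docstring for the scoring rule.

    Sequences shorter than the window get an all-zero profile.
    """
    if params is None:
        params = CoiledCoilParams()
    n = len(record.seq)
    W = params.window
    if n < W:
        import warnings

        warnings.warn(
            f"sequence {record.id!r} shorter than window {W}; all-zero profile",
            stacklevel=2,
        )
        zeros = np.zeros(n)
        return CoiledCoilProfile(zeros, zeros.copy(), [])

    # log-propensity of residue i at heptad position (i + f) % 7, per frame f
    prop = np.stack([params.propensity[c] for c in record.seq])  # (n, 7)
    logp = np.log(prop)
    pos = np.arange(n)
    best = np.full(n, -np.inf)
    for f in range(7):
        lp = logp[pos, (pos + f) % 7]
        csum = np.concatenate([[0.0], np.cumsum(lp)])
        wlog = (csum[W:] - csum[:-W]) / W  # mean log per window start
        best = np.maximum(best, _trailing_max(wlog, W, n))
    score = np.exp(best)
    prob = score_to_prob(score, params)
    profile = CoiledCoilProfile(per_residue_score=score, per_residue_prob=prob)
    profile.segments = cc_segments(profile)
    return profile


def cc_segments(
    profile: CoiledCoilProfile, p_min: float = 0.5, min_len: int = 21
) -> list[tuple[int, int, float]]:
    """Maximal runs with prob >= p_min and length >= min_len.

    Returned as 0-based half-open ``(start, end, mean_prob)`` tuples,
    sorted and non-overlapping.
    """
    mask = profile.per_residue_prob >= p_min
    segments: list[tuple[int, int, float]] = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                segments.append((i, j, float(profile.per_residue_prob[i:j].mean())))
            i = j
        else:
            i += 1
    return segments


def cc_fraction(profile: CoiledCoilProfile) -> float:
    """Fraction of residues inside coiled-coil segments."""
    n = profile.per_residue_prob.size
    if n == 0:
        return 0.0
    return sum(e - s for s, e, _ in profile.segments) / n


# ---------------------------------------------------------------------------
# Heptad-model sampling (shared by the simulator and the calibration script)
# ---------------------------------------------------------------------------

#: heptad-model sampling defaults: positional sharpening exponent and the
#: weight of the position-specific component over the shared low-complexity
#: composition.  Real coiled-coil/intermediate-filament sequences are
#: charged-repeat rich, so most of their alignment signal survives residue
#: shuffling; the weak positional tilt carries the a/d hydrophobic period.
HEPTAD_SHARPENING = 2.5
HEPTAD_WEIGHT = 0.35


def heptad_distributions(
    table: dict[str, np.ndarray],
    sharpening: float = HEPTAD_SHARPENING,
    heptad_weight: float = HEPTAD_WEIGHT,
) -> np.ndarray:
    """(7, 20) matrix: P(residue | heptad position).

    Sharpened propensity columns mixed with their position average, so
    the composition is low-complexity (E/K/L/A/Q-rich) and the
    positional preference (hydrophobics at a/d) is a tilt on top of it.
    """
    mat = np.stack([table[a] for a in AMINO_ACIDS])  # (20, 7)
    sharp = mat ** sharpening
    sharp = sharp / sharp.sum(axis=0, keepdims=True)
    marginal = sharp.mean(axis=1, keepdims=True)
    probs = (1.0 - heptad_weight) * marginal + heptad_weight * sharp
    return probs.T  # (7, 20)


def sample_heptad_sequence(
    length: int,
    frame: int,
    rng: np.random.Generator,
    table: dict[str, np.ndarray] | None = None,
    sharpening: float = HEPTAD_SHARPENING,
    heptad_weight: float = HEPTAD_WEIGHT,
) -> str:
    """Draw an idealized coiled-coil sequence from the heptad model."""
    if table is None:
        table = load_propensity_table()
    dists = heptad_distributions(table, sharpening, heptad_weight)
    out = []
    for i in range(length):
        d = dists[(i + frame) % 7]
        out.append(AMINO_ACIDS[rng.choice(20, p=d)])
    return "".join(out)


def calibrate_gaussians(
    window: int,
    background: np.ndarray,
    table: dict[str, np.ndarray] | None = None,
    n_windows: int = 4000,
    seed: int = 20260924,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fit the (mean, sd) of max-over-frame window scores for the two
    reference classes: heptad-model sequences and background-composition
    ("globular") sequences.

    Used once by scripts/calibrate_coils.py to produce the frozen
    constants; kept in the package so the calibration is reproducible.
    """
    if table is None:
        table = load_propensity_table()
    rng = np.random.default_rng(seed)
    params = CoiledCoilParams(window=window, propensity=table)

    def window_scores(seq: str) -> np.ndarray:
        prop = np.stack([table[c] for c in seq])
        logp = np.log(prop)
        pos = np.arange(len(seq))
        per_frame = []
        for f in range(7):
            lp = logp[pos, (pos + f) % 7]
            csum = np.concatenate([[0.0], np.cumsum(lp)])
            per_frame.append((csum[window:] - csum[:-window]) / window)
        return np.exp(np.max(np.stack(per_frame), axis=0))

    del params  # only validated the window
    cc_scores: list[float] = []
    gl_scores: list[float] = []
    seq_len = 10 * window
    n_seqs = max(1, n_windows // (seq_len - window + 1))
    for _ in range(n_seqs):
        frame = int(rng.integers(7))
        cc_scores.extend(window_scores(sample_heptad_sequence(seq_len, frame, rng, table)))
        gl = "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=seq_len, p=background))
        gl_scores.extend(window_scores(gl))
    cc_arr = np.array(cc_scores)
    gl_arr = np.array(gl_scores)
    return (
        (float(cc_arr.mean()), float(cc_arr.std(ddof=1))),
        (float(gl_arr.mean()), float(gl_arr.std(ddof=1))),
    )
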
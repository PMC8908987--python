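"""Markov-Gibbs random field (MGRF) energy descriptor.

A translation-invariant MGRF over quantised HU levels models the *normal*
(benign) nodule texture:  P(g) = (1/Z) exp(-E(g)).  The normaliser Z is never
needed because the feature is the per-voxel Gibbs energy itself; energy is low
where the voxel's neighbourhood statistics look like the training texture and
high where they deviate, so heterogeneous (malignant-like) interiors light up.

Clique structure (configurable):

* 13 symmetric pairwise offset families covering the 26-neighbourhood; the
  configuration of a pair is the ordered quantised level pair (q1, q2), and the
  independent-field reference frequency is 1/Q^2;
* one 7-voxel star family (centre plus its 6 face neighbours); its
  configuration is (q0, k) where k counts neighbours within +/-1 level of the
  centre, with the exact uniform-marginal binomial as reference.

Training uses the analytic first approximation of the maximum-likelihood
potentials: potential(cfg) = lambda * (F_emp(cfg) - F_ref(cfg)) with the
empirical frequencies pooled over the benign training nodules (lambda = 1).
The energy image assigns each in-mask voxel minus the summed potentials of all
cliques containing it; the descriptor is the normalised histogram of in-mask
energies over a global range fixed from the training-set energy percentiles
(0.5-99.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from ..volume import NoduleMask, VoxelVolume
from .base import DescriptorVector, NoduleDescriptor

__all__ = [
    "DEFAULT_OFFSETS",
    "MGRFModel",
    "train_mgrf",
    "gibbs_energy_image",
    "energy_histogram",
    "save_model_json",
    "load_model_json",
    "MGRFEnergyExtractor",
]

#: 13 offsets whose negations complete the 26-neighbourhood.
DEFAULT_OFFSETS: tuple = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_FACE_OFFSETS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


@dataclass
class MGRFModel:
    """Trained potentials plus the quantisation and histogram calibration."""

    q_levels: int
    offsets: tuple
    pair_potentials: dict                 # offset -> (Q, Q) array
    star_potential: np.ndarray | None     # (Q, 7) array or None
    hu_range: tuple                       # (lo, hi) HU used for quantisation
    energy_range: tuple = (0.0, 1.0)      # histogram range from training energies
    scale: float = 1.0                    # lambda in the centred-frequency MLE


def _quantize(data: np.ndarray, lo: float, hi: float, q: int) -> np.ndarray:
    if hi <= lo:
        return np.zeros(data.shape, dtype=np.int64)
    lev = np.floor((data - lo) / (hi - lo) * q).astype(np.int64)
    return np.clip(lev, 0, q - 1)


def _star_reference(q: int) -> np.ndarray:
    """F_ref(q0, k) for an independent uniform field: (1/Q) Binom(6, k; p(q0))."""
    out = np.empty((q, 7))
    for q0 in range(q):
        near = min(q0 + 1, q - 1) - max(q0 - 1, 0) + 1
        p = near / q
        for k in range(7):
            out[q0, k] = comb(6, k) * p**k * (1 - p) ** (6 - k) / q
    return out


def _pair_counts(levels, mask, offset, q):
    """Co-occurrence counts for one offset family, both endpoints in mask."""
    dx, dy, dz = offset
    sl0 = tuple(slice(max(d, 0), s + min(d, 0)) for d, s in zip((dx, dy, dz), levels.shape))
    sl1 = tuple(slice(max(-d, 0), s + min(-d, 0)) for d, s in zip((dx, dy, dz), levels.shape))
    # voxel v in sl1 pairs with v + offset in sl0
    a = levels[sl1]
    b = levels[sl0]
    m = mask[sl1] & mask[sl0]
    if not m.any():
        return np.zeros((q, q))
    idx = a[m] * q + b[m]
    return np.bincount(idx, minlength=q * q).reshape(q, q).astype(float)


def _star_config(levels, mask):
    """(q0, k) maps for star cliques; valid where centre + 6 face neighbours in mask."""
    pad_l = np.pad(levels, 1, mode="edge")
    pad_m = np.pad(mask, 1, mode="constant")
    core = (slice(1, -1),) * 3
    k = np.zeros(levels.shape, dtype=np.int64)
    valid = pad_m[core].copy()
    for dx, dy, dz in _FACE_OFFSETS:
        sl = (slice(1 + dx, levels.shape[0] + 1 + dx),
              slice(1 + dy, levels.shape[1] + 1 + dy),
              slice(1 + dz, levels.shape[2] + 1 + dz))
        valid &= pad_m[sl]
        k += np.abs(pad_l[sl] - levels) <= 1
    return levels, k, valid


def train_mgrf(
    training: list,
    q_levels: int = 32,
    offsets: tuple | None = None,
    include_star: bool = True,
    scale: float = 1.0,
    hist_bins: int = 1000,
) -> MGRFModel:
    """Fit the centred-frequency MLE potentials on benign training nodules.

    ``training`` is a list of ``(VoxelVolume, NoduleMask)`` pairs or objects
    with ``voi``/``mask`` attributes (e.g. :class:`NoduleRecord`).  Also fixes
    the global energy-histogram range from the training-set energies.
    """
    pairs = [(t.voi, t.mask) if hasattr(t, "voi") else t for t in training]
    if not pairs:
        raise ValueError("MGRF training requires at least one benign nodule")
    offsets = tuple(offsets) if offsets is not None else DEFAULT_OFFSETS
    pooled = np.concatenate([v.data[m.data] for v, m in pairs])
    lo, hi = np.percentile(pooled, [1.0, 99.0])
    q = int(q_levels)
    if q < 1:
        raise ValueError("q_levels must be >= 1")
    pair_counts = {o: np.zeros((q, q)) for o in offsets}
    star_counts = np.zeros((q, 7))
    for vol, msk in pairs:
        levels = _quantize(vol.data, lo, hi, q)
        inm = msk.data
        for o in offsets:
            pair_counts[o] += _pair_counts(levels, inm, o, q)
        if include_star:
            q0, k, valid = _star_config(levels, inm)
            if valid.any():
                idx = q0[valid] * 7 + k[valid]
                star_counts += np.bincount(idx, minlength=q * 7).reshape(q, 7)
    pair_pot = {}
    for o, cnt in pair_counts.items():
        total = cnt.sum()
        f_emp = cnt / total if total > 0 else np.full((q, q), 1.0 / q**2)
        pair_pot[o] = scale * (f_emp - 1.0 / q**2)
    star_pot = None
    if include_star:
        total = star_counts.sum()
        ref = _star_reference(q)
        f_emp = star_counts / total if total > 0 else ref
        star_pot = scale * (f_emp - ref)
    model = MGRFModel(
        q_levels=q, offsets=offsets, pair_potentials=pair_pot,
        star_potential=star_pot, hu_range=(float(lo), float(hi)), scale=scale,
    )
    # calibrate the global histogram range on the training energies
    energies = np.concatenate(
        [gibbs_energy_image(v, m, model)[m.data] for v, m in pairs]
    )
    e_lo, e_hi = np.percentile(energies, [0.5, 99.5])
    if e_hi <= e_lo:
        e_hi = e_lo + 1e-9
    model.energy_range = (float(e_lo), float(e_hi))
    return model


def gibbs_energy_image(voi: VoxelVolume, mask: NoduleMask, model: MGRFModel) -> np.ndarray:
    """Per-voxel Gibbs energy: minus the summed potentials of incident cliques.

    Voxels outside the mask are zero.  A pairwise clique contributes its
    potential to both endpoints; a star clique to all seven members.
    """
    if voi.shape != mask.shape:
        raise ValueError("VOI and mask shapes differ")
    levels = _quantize(voi.data, *model.hu_range, model.q_levels)
    inm = mask.data
    energy = np.zeros(voi.shape)
    for o, pot in model.pair_potentials.items():
        dx, dy, dz = o
        sl0 = tuple(slice(max(d, 0), s + min(d, 0)) for d, s in zip(o, levels.shape))
        sl1 = tuple(slice(max(-d, 0), s + min(-d, 0)) for d, s in zip(o, levels.shape))
        both = inm[sl1] & inm[sl0]
        contrib = np.where(both, pot[levels[sl1], levels[sl0]], 0.0)
        energy[sl1] -= contrib
        energy[sl0] -= contrib
    if model.star_potential is not None:
        q0, k, valid = _star_config(levels, inm)
        contrib = np.where(valid, model.star_potential[q0, np.clip(k, 0, 6)], 0.0)
        energy -= contrib  # the centre
        padded = np.pad(contrib, 1)
        for dx, dy, dz in _FACE_OFFSETS:
            sl = (slice(1 - dx, energy.shape[0] + 1 - dx),
                  slice(1 - dy, energy.shape[1] + 1 - dy),
                  slice(1 - dz, energy.shape[2] + 1 - dz))
            energy -= padded[sl]  # the six members
    energy[~inm] = 0.0
    return energy


def energy_histogram(
    energy: np.ndarray,
    mask: NoduleMask,
    n_bins: int = 1000,
    energy_range: tuple | None = None,
) -> DescriptorVector:
    """Normalised histogram of in-mask energies over a fixed global range."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = np.asarray(energy)[mask.data]
    rng = energy_range if energy_range is not None else (float(vals.min()), float(vals.max()) + 1e-9)
    hist, _ = np.histogram(np.clip(vals, rng[0], rng[1]), bins=n_bins, range=rng)
    hist = hist.astype(float)
    total = hist.sum()
    if total > 0:
        hist /= total
    names = [f"mgrf_{b}" for b in range(n_bins)]
    return DescriptorVector(values=hist, tag="mgrf", names=names)


def save_model_json(model: MGRFModel, path: str) -> None:
    """Serialise a trained model (families, Q, ranges, potential tables)."""
    import json

    payload = {
        "q_levels": model.q_levels,
        "offsets": [list(o) for o in model.offsets],
        "pair_potentials": {",".join(map(str, o)): p.tolist()
                            for o, p in model.pair_potentials.items()},
        "star_potential": None if model.star_potential is None else model.star_potential.tolist(),
        "hu_range": list(model.hu_range),
        "energy_range": list(model.energy_range),
        "scale": model.scale,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_json(path: str) -> MGRFModel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    offsets = tuple(tuple(o) for o in d["offsets"])
    return MGRFModel(
        q_levels=d["q_levels"],
        offsets=offsets,
        pair_potentials={tuple(map(int, k.split(","))): np.asarray(v)
                         for k, v in d["pair_potentials"].items()},
        star_potential=None if d["star_potential"] is None else np.asarray(d["star_potential"]),
        hu_range=tuple(d["hu_range"]),
        energy_range=tuple(d["energy_range"]),
        scale=d["scale"],
    )


class MGRFEnergyExtractor(NoduleDescriptor):
    """Gibbs-energy histogram as a transformer; ``fit`` trains on benign records."""

    tag = "mgrf"

    def __init__(self, q_levels: int = 32, n_bins: int = 1000, include_star: bool = True,
                 scale: float = 1.0):
        self.q_levels = q_levels
        self.n_bins = n_bins
        self.include_star = include_star
        self.scale = scale

    def fit(self, records, y=None):
        """Train on the benign subset of ``records`` (all records if unlabeled)."""
        benign = [r for r in records if getattr(r, "label", "benign") == "benign"]
        if not benign:
            raise ValueError("MGRF training requires at least one benign nodule")
        self.model_ = train_mgrf(
            benign, q_levels=self.q_levels, include_star=self.include_star, scale=self.scale
        )
        return self

    def describe(self, record) -> DescriptorVector:
        if not hasattr(self, "model_"):
            raise RuntimeError("MGRFEnergyExtractor must be fitted before transform")
        energy = gibbs_energy_image(record.voi, record.mask, self.model_)
        return energy_histogram(energy, record.mask, n_bins=self.n_bins,
                                energy_range=self.model_.energy_range)
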
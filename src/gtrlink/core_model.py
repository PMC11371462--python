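"""Amino-acid substitution machinery for linked-GTR profile mixture models.

A time-reversible rate matrix for a mixture class is assembled from a single
exchangeability matrix ``S`` shared across classes and a class-specific
stationary profile ``pi``:

    q_ij = s_ij * pi_j   (i != j),   q_ii = -sum_{j != i} q_ij,

rescaled so that the mean instantaneous rate ``-sum_i pi_i q_ii`` equals one,
which makes branch lengths interpretable as expected substitutions per site.
Because ``S`` and ``cS`` (c > 0) yield the same normalized rate matrix, one
entry is conventionally pinned: the tyrosine/valine exchangeability is fixed
at 1 during estimation, leaving 189 free exchangeability parameters.

This module also provides the comparison transform used to place two
exchangeability matrices on a common scale (their rate matrices under the
uniform profile, off-diagonals normalized to total mass one) and the SAD
(sum of absolute differences) pseudometric computed on that scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "Alphabet",
    "ALPHABET",
    "ExchangeabilityMatrix",
    "Profile",
    "ProfileMixture",
    "RateMatrix",
    "build_rate_matrix",
    "transition_matrix",
    "stationary_ergodic_check",
    "empirical_profile",
    "comparison_form",
    "sad",
    "poisson_matrix",
    "lg_matrix",
    "lg_profile",
    "read_paml_dat",
    "write_paml_dat",
    "read_profile_table",
    "write_profile_table",
    "write_nexus_matrix",
    "read_nexus_profiles",
]

#: Standard PAML residue order; position 19 (1-based) is Y, position 20 is V.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_VALIDATION_TOL = 1e-10

#: Constrained entry, 0-based: (Y, V) == (18, 19), pinned to 1 in estimation.
CONSTRAINED_PAIR = (18, 19)


class Alphabet:
    """The 20-letter amino-acid alphabet in fixed PAML order."""

    def __init__(self, symbols: str = AMINO_ACIDS):
        symbols = str(symbols)
        if len(symbols) != 20 or len(set(symbols)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct symbols")
        self.symbols = symbols
        self.index = {s: i for i, s in enumerate(symbols)}

    def __len__(self) -> int:
        return 20

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index


ALPHABET = Alphabet()

#: Characters treated as fully missing data in alignments.
MISSING_CHARS = set("-?.XBZJ*")


def _as_matrix(entries) -> np.ndarray:
    m = np.asarray(entries, dtype=float)
    if m.shape != (20, 20):
        raise ValueError(f"expected a 20x20 matrix, got shape {m.shape}")
    return m


@dataclass(frozen=True)
class ExchangeabilityMatrix:
    """Symmetric non-negative matrix of relative amino-acid exchange rates.

    The diagonal is unused and stored as zero.  ``name`` is a display label
    ("LG", "POISSON", an output-file stem, ...).
    """

    entries: np.ndarray
    name: str = ""

    def __post_init__(self):
        m = _as_matrix(self.entries).copy()
        np.fill_diagonal(m, 0.0)
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("exchangeabilities must be finite and non-negative")
        scale = max(m.max(), 1.0)
        if not np.allclose(m, m.T, atol=_VALIDATION_TOL * scale, rtol=0):
            raise ValueError("exchangeability matrix must be symmetric")
        m = 0.5 * (m + m.T)
        m.setflags(write=False)
        object.__setattr__(self, "entries", m)

    def upper_triangle(self) -> np.ndarray:
        """The 190 distinct entries, ordered (0,1), (0,2), ..., (18,19)."""
        iu = np.triu_indices(20, k=1)
        return self.entries[iu]

    @classmethod
    def from_upper_triangle(cls, values, name: str = "") -> "ExchangeabilityMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (190,):
            raise ValueError("expected 190 upper-triangle values")
        m = np.zeros((20, 20))
        iu = np.triu_indices(20, k=1)
        m[iu] = values
        m += m.T
        return cls(m, name=name)

    def constrained(self) -> "ExchangeabilityMatrix":
        """Rescale so the (Y, V) entry equals 1 exactly."""
        i, j = CONSTRAINED_PAIR
        ref = self.entries[i, j]
        if ref <= 0:
            raise ValueError("cannot constrain: the Y/V exchangeability is zero")
        return ExchangeabilityMatrix(self.entries / ref, name=self.name)

    @property
    def is_constrained(self) -> bool:
        i, j = CONSTRAINED_PAIR
        return self.entries[i, j] == 1.0


@dataclass(frozen=True)
class Profile:
    """A vector of 20 equilibrium amino-acid frequencies."""

    freqs: np.ndarray
    name: str = ""

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (20,):
            raise ValueError("profile must have 20 frequencies")
        if np.any(f < 0) or not np.all(np.isfinite(f)):
            raise ValueError("profile frequencies must be finite and non-negative")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError(f"profile frequencies must sum to 1 (got {f.sum():.12g})")
        f = f / f.sum()
        f.setflags(write=False)
        object.__setattr__(self, "freqs", f)

    @classmethod
    def uniform(cls) -> "Profile":
        return cls(np.full(20, 0.05), name="uniform")


@dataclass(frozen=True)
class ProfileMixture:
    """C profiles with positive weights summing to one."""

    profiles: tuple
    weights: np.ndarray
    weights_mode: str = "fixed"  # "fixed" or "estimated"

    def __post_init__(self):
        profiles = tuple(self.profiles)
        if len(profiles) < 1:
            raise ValueError("mixture needs at least one profile")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(profiles),):
            raise ValueError("one weight per profile required")
        if np.any(w <= 0):
            raise ValueError("mixture weights must be positive")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if self.weights_mode not in ("fixed", "estimated"):
            raise ValueError("weights_mode must be 'fixed' or 'estimated'")
        w = w / w.sum()
        w.setflags(write=False)
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(self, "weights", w)

    @property
    def n_classes(self) -> int:
        return len(self.profiles)

    @classmethod
    def single(cls, profile: Profile) -> "ProfileMixture":
        return cls((profile,), np.array([1.0]))

    def with_weights(self, weights, weights_mode=None) -> "ProfileMixture":
        return ProfileMixture(self.profiles, np.asarray(weights, float),
                              weights_mode or self.weights_mode)

    def with_f_class(self, profile: Profile, weight: float | None = None) -> "ProfileMixture":
        """Append an empirical-frequency ("+F") class, rescaling old weights."""
        c = self.n_classes
        w_new = 1.0 / (c + 1) if weight is None else float(weight)
        w = np.concatenate([self.weights * (1.0 - w_new), [w_new]])
        return ProfileMixture(self.profiles + (profile,), w, self.weights_mode)


@dataclass(frozen=True)
class RateMatrix:
    """Normalized time-reversible instantaneous rate matrix for one profile.

    Mean rate is one: ``-sum_i pi_i q_ii == 1``.  The eigendecomposition of
    the symmetrized form ``diag(sqrt pi) Q diag(1/sqrt pi)`` is cached lazily
    for fast, stable transition probabilities.
    """

    entries: np.ndarray
    profile: Profile
    _eig: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        m = _as_matrix(self.entries).copy()
        m.setflags(write=False)
        object.__setattr__(self, "entries", m)

    def eig(self):
        """(U, lam, sqrt_pi) with B = diag(s) Q diag(1/s) = U diag(lam) U^T."""
        if "U" not in self._eig:
            pi = self.profile.freqs
            if np.any(pi <= 0):
                raise ValueError("eigendecomposition requires a strictly positive profile")
            s = np.sqrt(pi)
            b = self.entries * (s[:, None] / s[None, :])
            b = 0.5 * (b + b.T)  # symmetric up to round-off
            lam, u = np.linalg.eigh(b)
            self._eig["U"] = u
            self._eig["lam"] = lam
            self._eig["s"] = s
        return self._eig["U"], self._eig["lam"], self._eig["s"]


def build_rate_matrix(S: ExchangeabilityMatrix, pi: Profile) -> RateMatrix:
    """Assemble the normalized reversible rate matrix ``Q`` from ``S`` and ``pi``.

    Off-diagonals are ``s_ij * pi_j``; the diagonal makes rows sum to zero;
    the whole matrix is rescaled to unit mean rate.  The result satisfies
    stationarity (``pi Q = 0``) and detailed balance (``diag(pi) Q`` symmetric)
    by construction, and is invariant to positive rescaling of ``S``.
    """
    if not isinstance(S, ExchangeabilityMatrix):
        S = ExchangeabilityMatrix(S)
    if not isinstance(pi, Profile):
        pi = Profile(np.asarray(pi, float))
    f = pi.freqs
    q = S.entries * f[None, :]
    np.fill_diagonal(q, 0.0)
    q[np.diag_indices(20)] = -q.sum(axis=1)
    mean_rate = -float(np.dot(f, np.diag(q)))
    if mean_rate <= 1e-14:
        raise ValueError("degenerate rate matrix: zero mean substitution rate")
    return RateMatrix(q / mean_rate, pi)


def transition_matrix(Q: RateMatrix, t: float) -> np.ndarray:
    """Transition probabilities ``P = exp(Q t)`` over branch length ``t``.

    Computed through the eigendecomposition of the symmetrized rate matrix;
    tiny negative round-off is clamped to zero and rows renormalized.
    """
    t = float(t)
    if not np.isfinite(t) or t < 0:
        raise ValueError("branch length must be finite and non-negative")
    if t == 0.0:
        return np.eye(20)
    u, lam, s = Q.eig()
    p = (u * np.exp(lam * t)) @ u.T
    p *= s[None, :] / s[:, None]
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def stationary_ergodic_check(Q: RateMatrix, tol: float = 1e-6) -> bool:
    """True if ``P(t)`` rows converge to the profile for large ``t``."""
    p = transition_matrix(Q, 1e4)
    return bool(np.max(np.abs(p - Q.profile.freqs[None, :])) < tol)


def empirical_profile(aln, pseudocount: float = 0.5, name: str = "F") -> Profile:
    """Observed residue frequencies of an alignment (the "+F" class profile).

    Gaps and ambiguity codes are ignored.  ``pseudocount`` is added to every
    residue count before normalizing so that unobserved residues keep a small
    positive frequency (required for an irreducible rate matrix); pass 0 to
    disable.
    """
    counts = np.zeros(20)
    for row in aln.rows:
        for ch in row:
            i = ALPHABET.index.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no countable amino-acid residues")
    counts += float(pseudocount)
    return Profile(counts / counts.sum(), name=name)


def comparison_form(S: ExchangeabilityMatrix) -> np.ndarray:
    """Transform ``S`` to the 190-vector used for cross-matrix comparison.

    Builds the rate matrix under the uniform profile, normalizes its 380
    off-diagonal entries to total mass one, and returns the 190 distinct
    (upper-triangle) entries.  Invariant to positive rescaling of ``S``.
    """
    if not isinstance(S, ExchangeabilityMatrix):
        S = ExchangeabilityMatrix(S)
    q = build_rate_matrix(S, Profile.uniform()).entries.copy()
    np.fill_diagonal(q, 0.0)
    iu = np.triu_indices(20, k=1)
    return q[iu] / q.sum()


def sad(S1: ExchangeabilityMatrix, S2: ExchangeabilityMatrix) -> float:
    """Sum of absolute differences between two matrices on the comparison scale.

    A pseudometric: symmetric, satisfies the triangle inequality, and is zero
    between a matrix and any positive rescaling of itself.
    """
    return float(np.abs(comparison_form(S1) - comparison_form(S2)).sum())


# ---------------------------------------------------------------------------
# Bundled matrices
# ---------------------------------------------------------------------------

def poisson_matrix() -> ExchangeabilityMatrix:
    """The POISSON matrix: every off-diagonal exchangeability equal to one."""
    return ExchangeabilityMatrix(np.ones((20, 20)), name="POISSON")


def _load_lg():
    path = importlib.resources.files("gtrlink.data") / "lg.dat"
    with importlib.resources.as_file(path) as p:
        return read_paml_dat(p)


_LG_CACHE: list = []


def lg_matrix() -> ExchangeabilityMatrix:
    """The published LG exchangeability matrix (Le & Gascuel 2008)."""
    if not _LG_CACHE:
        _LG_CACHE.extend(_load_lg())
    return _LG_CACHE[0]


def lg_profile() -> Profile:
    """The stationary amino-acid frequencies published with LG."""
    if not _LG_CACHE:
        _LG_CACHE.extend(_load_lg())
    return _LG_CACHE[1]


# ---------------------------------------------------------------------------
# File formats: PAML-dat matrices, profile tables
# ---------------------------------------------------------------------------

def read_paml_dat(path) -> tuple[ExchangeabilityMatrix, Profile | None]:
    """Read a PAML-dat exchangeability file.

    Layout: 19 whitespace-separated lower-triangle rows (row ``i`` holds the
    ``i`` exchangeabilities against residues ``1..i``), optionally followed by
    a row of 20 stationary frequencies.  ``#`` starts a comment.
    """
    numbers: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for tok in line.split():
                try:
                    numbers.append(float(tok))
                except ValueError as exc:
                    raise ValueError(f"{path}: non-numeric token {tok!r}") from exc
    if len(numbers) not in (190, 210):
        raise ValueError(
            f"{path}: expected 190 exchangeabilities (+ optional 20 frequencies), "
            f"got {len(numbers)} numbers")
    m = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            m[i, j] = m[j, i] = numbers[k]
            k += 1
    name = str(getattr(path, "stem", path))
    S = ExchangeabilityMatrix(m, name=name)
    freqs = None
    if len(numbers) == 210:
        freqs = Profile(np.array(numbers[190:]), name=name)
    return S, freqs


def write_paml_dat(path, S: ExchangeabilityMatrix, freqs: Profile | None = None) -> None:
    """Write ``S`` (and optional frequencies) in PAML-dat layout, 10 sig. digits."""
    lines = []
    m = S.entries
    for i in range(1, 20):
        lines.append(" ".join(f"{m[i, j]:.10g}" for j in range(i)))
    if freqs is not None:
        lines.append(" ".join(f"{f:.10g}" for f in freqs.freqs))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_profile_table(path) -> ProfileMixture:
    """Read a TSV profile set: optional header, one profile per row.

    Rows have 20 frequency columns, optionally preceded by a weight column
    (detected when rows have 21 numeric fields).  Without weights, classes
    get equal weights.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", "\t").split()
            try:
                rows.append([float(x) for x in fields])
            except ValueError:
                continue  # header line
    if not rows:
        raise ValueError(f"{path}: no numeric profile rows found")
    widths = {len(r) for r in rows}
    if widths == {20}:
        profiles = [Profile(np.array(r)) for r in rows]
        weights = np.full(len(rows), 1.0 / len(rows))
    elif widths == {21}:
        weights = np.array([r[0] for r in rows])
        weights = weights / weights.sum()
        profiles = [Profile(np.array(r[1:])) for r in rows]
    else:
        raise ValueError(f"{path}: rows must have 20 (or weight+20) columns, got {widths}")
    return ProfileMixture(tuple(profiles), weights)


def write_profile_table(path, mixture: ProfileMixture) -> None:
    with open(path, "w") as fh:
        fh.write("weight\t" + "\t".join(AMINO_ACIDS) + "\n")
        for w, p in zip(mixture.weights, mixture.profiles):
            fh.write(f"{w:.10g}\t" + "\t".join(f"{x:.10g}" for x in p.freqs) + "\n")


def write_nexus_matrix(path, S: ExchangeabilityMatrix,
                       freqs: Profile | None = None,
                       name: str = "LINKED") -> None:
    """Write ``S`` as a NEXUS-style model block.

    The model line lists the 190 lower-triangle exchangeabilities in PAML
    order followed by 20 stationary frequencies (uniform when none are
    given), the layout common ML phylogenetics software accepts for
    user-defined amino-acid models.
    """
    vals = []
    m = S.entries
    for i in range(1, 20):
        vals.extend(m[i, j] for j in range(i))
    f = freqs.freqs if freqs is not None else np.full(20, 0.05)
    body = " ".join(f"{v:.10g}" for v in list(vals) + list(f))
    with open(path, "w") as fh:
        fh.write("#nexus\nbegin models;\n")
        fh.write(f"  model {name} = {body};\n")
        fh.write("end;\n")


def read_nexus_profiles(path) -> ProfileMixture:
    """Read frequency-vector classes from a NEXUS-style model block.

    Recognizes lines of the form ``frequency <name> = f1 ... f20;`` inside
    the file, as emitted by common ML phylogenetics software for custom
    profile mixtures.  Classes get equal weights.
    """
    import re

    text = open(path).read()
    profiles = []
    for match in re.finditer(r"frequency\s+(\S+)\s*=\s*([^;]+);", text, re.IGNORECASE):
        name, body = match.group(1), match.group(2)
        vals = [float(x) for x in body.split()]
        if len(vals) != 20:
            raise ValueError(f"{path}: class {name} has {len(vals)} frequencies, expected 20")
        profiles.append(Profile(np.array(vals) / np.sum(vals), name=name))
    if not profiles:
        raise ValueError(f"{path}: no 'frequency <name> = ...;' definitions found")
    w = np.full(len(profiles), 1.0 / len(profiles))
    return ProfileMixture(tuple(profiles), w)
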
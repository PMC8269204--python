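"""Profile hidden Markov models for halogenase homology screening.

A profile HMM is estimated from a seed multiple alignment: columns whose gap
fraction is below a threshold become match states; emissions and state-path
transitions are estimated with Laplace (add-one-style) pseudocounts.  Scoring
is local-in-sequence and local-in-model, with a uniform entry distribution
over match states, mirroring the defaults of standard domain-search tools.

Scores are log2 odds of the forward (or Viterbi) probability against an
i.i.d. background model.  E-values come from an explicit Gumbel calibration
on background-sampled sequences rather than from a pre-fit tail distribution,
so absolute E-values are not interchangeable with HMMER's; the screening
thresholds are therefore exposed as parameters everywhere.

Dynamic programming is vectorized over model states; delete-state chains are
resolved with a prefix-scan so each query residue costs O(L) vector work.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import AMINO_ACIDS, MultipleAlignment, SequenceRecord

LN2 = math.log(2.0)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
NEG_INF = -np.inf

SCHEMA_VERSION = 1


class ModelError(ValueError):
    """The MSA cannot support a profile (e.g. no qualifying match columns)."""


class CalibrationError(RuntimeError):
    """E-value calibration failed (e.g. degenerate score distribution)."""


def encode(residues: str) -> np.ndarray:
    """Map residues to emission indices; 'X' becomes -1 (background)."""
    return np.fromiter(
        (_AA_INDEX.get(c, -1) for c in residues), dtype=np.int64, count=len(residues)
    )


@dataclass
class ProfileHMM:
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L, 20)
    # transitions[l] applies leaving node l (0-based); each row sums to 1
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_id: np.ndarray
    t_dm: np.ndarray
    t_di: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray  # (20,)
    column_map: np.ndarray  # (L,) 1-based source MSA columns, strictly increasing

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.n_match_states
        if L < 1:
            raise ModelError("profile has no match states")
        if not np.all(np.diff(self.column_map) > 0):
            raise ModelError("column_map is not strictly increasing")
        for name in ("match_emissions", "insert_emissions"):
            rows = getattr(self, name)
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ModelError(f"{name} rows do not sum to 1")
        trans = np.column_stack([self.t_mm + self.t_mi + self.t_md,
                                 self.t_im + self.t_ii + self.t_id,
                                 self.t_dm + self.t_di + self.t_dd])
        if not np.allclose(trans, 1.0, atol=1e-9):
            raise ModelError("transition distributions do not sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-9):
            raise ModelError("background does not sum to 1")

    def consensus(self) -> str:
        """Column-wise argmax consensus over match states."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {"schema_version": SCHEMA_VERSION}
        for name in ("match_emissions", "insert_emissions", "t_mm", "t_mi", "t_md",
                     "t_im", "t_ii", "t_id", "t_dm", "t_di", "t_dd", "background"):
            payload[name] = getattr(self, name).tolist()
        payload["column_map"] = self.column_map.tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        payload = json.loads(text)
        version = payload.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ModelError(f"unsupported model schema version {version!r}")
        kwargs = {k: np.asarray(v, dtype=float) for k, v in payload.items()
                  if k != "column_map"}
        kwargs["column_map"] = np.asarray(payload["column_map"], dtype=np.int64)
        model = cls(**kwargs)
        model.validate()
        return model


@dataclass(frozen=True)
class ScanHit:
    query_id: str
    bit_score: float
    e_value: float
    model_coverage: float
    aligned_interval: tuple[int, int]  # 1-based inclusive on the query

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if not 0.0 <= self.model_coverage <= 1.0:
            raise ValueError("model_coverage must lie in [0, 1]")


@dataclass
class ViterbiAlignment:
    score_bits: float
    path: list[tuple[str, int, int | None]]  # (state, model node 1-based, query pos 1-based)
    model_coverage: float
    aligned_interval: tuple[int, int]
    match_map: dict[int, int]  # match state (1-based) -> query position (1-based)


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def msa_background(msa: MultipleAlignment) -> np.ndarray:
    counts = np.zeros(20)
    for row in msa.rows:
        for c in row:
            i = _AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return uniform_background()
    return counts / counts.sum()


def build_phmm(
    msa: MultipleAlignment,
    gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns with gap fraction strictly below ``gap_threshold`` become match
    states.  Emission probabilities for a column are
    ``(count + pseudocount) / (n_observed + 20 * pseudocount)`` where
    ``n_observed`` counts rows with a canonical residue in that column ('X'
    contributes to neither numerator nor denominator).  Transition counts are
    accumulated from each row's match/insert/delete state path and smoothed
    with the same pseudocount over the three successors of every node.
    """
    if msa.n_rows < 2:
        raise ModelError("profile building needs at least 2 alignment rows")
    if pseudocount <= 0:
        raise ModelError("pseudocount must be positive")
    n_rows, n_cols = msa.n_rows, msa.n_cols
    cols = [msa.column(c) for c in range(1, n_cols + 1)]
    gap_frac = np.array([sum(ch == "-" for ch in col) / n_rows for col in cols])
    match_cols = [c for c in range(n_cols) if gap_frac[c] < gap_threshold]
    L = len(match_cols)
    if L == 0:
        raise ModelError("no columns qualify as match states under the gap threshold")

    match_counts = np.zeros((L, 20))
    insert_counts = np.zeros((L, 20))
    match_col_index = {c: l for l, c in enumerate(match_cols)}
    for l, c in enumerate(match_cols):
        for ch in cols[c]:
            i = _AA_INDEX.get(ch)
            if i is not None:
                match_counts[l, i] += 1

    # transition counts, per node l: rows (from-state M/I/D) x (to M/I/D)
    tc = np.zeros((L, 3, 3))
    _M, _I, _D = 0, 1, 2
    for row in msa.rows:
        state, node = None, None  # state at current node
        for c in range(n_cols):
            ch = row[c]
            if c in match_col_index:
                l = match_col_index[c]
                new_state = _M if ch != "-" else _D
                if state is not None:
                    tc[node, state, new_state] += 1
                state, node = new_state, l
            else:
                if ch == "-" or state is None:
                    continue  # gap in insert column, or leading insert (local entry)
                if node < L - 1:  # inserts after the final node lie outside the local path
                    i = _AA_INDEX.get(ch)
                    if i is not None:
                        insert_counts[node, i] += 1
                    tc[node, state, _I] += 1
                    state = _I

    denom = match_counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    match_emissions = (match_counts + pseudocount) / denom
    ins_denom = insert_counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    insert_emissions = (insert_counts + pseudocount) / ins_denom

    smoothed = (tc + pseudocount) / (tc.sum(axis=2, keepdims=True) + 3 * pseudocount)
    model = ProfileHMM(
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        t_mm=smoothed[:, _M, _M].copy(), t_mi=smoothed[:, _M, _I].copy(), t_md=smoothed[:, _M, _D].copy(),
        t_im=smoothed[:, _I, _M].copy(), t_ii=smoothed[:, _I, _I].copy(), t_id=smoothed[:, _I, _D].copy(),
        t_dm=smoothed[:, _D, _M].copy(), t_di=smoothed[:, _D, _I].copy(), t_dd=smoothed[:, _D, _D].copy(),
        background=uniform_background() if background is None else np.asarray(background, dtype=float),
        column_map=np.asarray([c + 1 for c in match_cols], dtype=np.int64),
    )
    model.validate()
    return model


def _log_odds(model: ProfileHMM):
    bg = model.background
    em = np.log(model.match_emissions) - np.log(bg)[None, :]
    ins = np.log(model.insert_emissions) - np.log(bg)[None, :]
    # 'X' (index -1) scores as background: odds 0
    em = np.column_stack([em, np.zeros(em.shape[0])])
    ins = np.column_stack([ins, np.zeros(ins.shape[0])])
    with np.errstate(divide="ignore"):
        lt = {name: np.log(getattr(model, name)) for name in
              ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_id", "t_dm", "t_di", "t_dd")}
    return em, ins, lt


def _forward_matrix(model: ProfileHMM, query: SequenceRecord):
    """Log-odds forward over local alignments; returns terminal log-odds (nats)."""
    em, ins, lt = _log_odds(model)
    L = model.n_match_states
    x = encode(query.residues)
    n = len(x)
    entry = -math.log(L)
    mm, mi, md = lt["t_mm"], lt["t_mi"], lt["t_md"]
    im, ii, id_ = lt["t_im"], lt["t_ii"], lt["t_id"]
    dm, di, dd = lt["t_dm"], lt["t_di"], lt["t_dd"]
    # C[l] = sum of delete-extension logs dd[0..l-1]; the chain entering D at
    # node k+1 and leaving at node l accumulates C[l] - C[k+1]
    C = np.concatenate([[0.0], np.cumsum(dd)])

    M_prev = np.full(L, NEG_INF)
    I_prev = np.full(L, NEG_INF)
    D_prev = np.full(L, NEG_INF)
    total = NEG_INF
    for i in range(n):
        # into M_l: fresh entry, or M/I/D at node l-1 one query position back
        prev = np.logaddexp(
            np.logaddexp(_shift(M_prev + mm), _shift(I_prev + im)),
            _shift(D_prev + dm),
        )
        M_cur = em[:, x[i]] + np.logaddexp(prev, entry)
        I_cur = ins[:, x[i]] + np.logaddexp(
            np.logaddexp(M_prev + mi, I_prev + ii), D_prev + di
        )
        # delete chain within this query position, as a prefix scan over nodes
        b = np.logaddexp(M_cur + md, I_cur + id_) - C[1:]
        acc = np.logaddexp.accumulate(b)
        D_cur = np.full(L, NEG_INF)
        D_cur[1:] = C[1:L] + acc[: L - 1]
        total = np.logaddexp(total, _lse(M_cur))
        M_prev, I_prev, D_prev = M_cur, I_cur, D_cur
    return total


def _shift(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v)
    out[0] = NEG_INF
    out[1:] = v[:-1]
    return out


def _lse(v: np.ndarray) -> float:
    m = v.max()
    if m == NEG_INF:
        return NEG_INF
    return m + math.log(np.exp(v - m).sum())


def forward_score(model: ProfileHMM, query: SequenceRecord) -> float:
    """Forward log2-odds score (bits) of the query against the profile.

    Sums over all local alignments that use at least one match state; the
    unaligned flanks are emitted by the background and cancel in the odds
    ratio.
    """
    if not query.residues:
        raise ValueError("query is empty")
    return _forward_matrix(model, query) / LN2


def viterbi_align(model: ProfileHMM, query: SequenceRecord) -> ViterbiAlignment:
    """Maximum-probability local state path and derived coverage statistics."""
    if not query.residues:
        raise ValueError("query is empty")
    em, ins, lt = _log_odds(model)
    L = model.n_match_states
    x = encode(query.residues)
    n = len(x)
    entry = -math.log(L)
    mm, mi, md = lt["t_mm"], lt["t_mi"], lt["t_md"]
    im, ii, id_ = lt["t_im"], lt["t_ii"], lt["t_id"]
    dm, di, dd = lt["t_dm"], lt["t_di"], lt["t_dd"]
    C = np.concatenate([[0.0], np.cumsum(dd)])

    M = np.full((n, L), NEG_INF)
    I = np.full((n, L), NEG_INF)
    D = np.full((n, L), NEG_INF)
    M_prev = np.full(L, NEG_INF)
    I_prev = np.full(L, NEG_INF)
    D_prev = np.full(L, NEG_INF)
    for i in range(n):
        prev = np.maximum(np.maximum(_shift(M_prev + mm), _shift(I_prev + im)),
                          _shift(D_prev + dm))
        M_cur = em[:, x[i]] + np.maximum(prev, entry)
        I_cur = ins[:, x[i]] + np.maximum(np.maximum(M_prev + mi, I_prev + ii),
                                          D_prev + di)
        b = np.maximum(M_cur + md, I_cur + id_) - C[1:]
        acc = np.maximum.accumulate(b)
        D_cur = np.full(L, NEG_INF)
        D_cur[1:] = C[1:L] + acc[: L - 1]
        M[i], I[i], D[i] = M_cur, I_cur, D_cur
        M_prev, I_prev, D_prev = M_cur, I_cur, D_cur

    flat = int(np.argmax(M))
    i, l = divmod(flat, L)
    score = M[i, l] / LN2

    # traceback by locally recomputing predecessor scores
    path: list[tuple[str, int, int | None]] = []
    state = "M"
    while True:
        if state == "M":
            path.append(("M", l + 1, i + 1))
            e = em[l, x[i]]
            cands = [entry]
            if i > 0 and l > 0:
                cands += [M[i - 1, l - 1] + mm[l - 1], I[i - 1, l - 1] + im[l - 1],
                          D[i - 1, l - 1] + dm[l - 1]]
            else:
                cands += [NEG_INF, NEG_INF, NEG_INF]
            k = int(np.argmax(cands))
            if k == 0:
                break
            i, l, state = i - 1, l - 1, "MID"[k - 1]
        elif state == "I":
            path.append(("I", l + 1, i + 1))
            cands = [M[i - 1, l] + mi[l], I[i - 1, l] + ii[l], D[i - 1, l] + di[l]] \
                if i > 0 else [NEG_INF] * 3
            k = int(np.argmax(cands))
            i, state = i - 1, "MID"[k]
        else:  # D: consumes no query residue
            path.append(("D", l + 1, None))
            cands = [M[i, l - 1] + md[l - 1], I[i, l - 1] + id_[l - 1],
                     D[i, l - 1] + dd[l - 1]] if l > 0 else [NEG_INF] * 3
            k = int(np.argmax(cands))
            l, state = l - 1, "MID"[k]
    path.reverse()

    match_map = {node: q for st, node, q in path if st == "M"}
    coverage = len(match_map) / L
    q_positions = [q for _, _, q in path if q is not None]
    interval = (min(q_positions), max(q_positions))
    return ViterbiAlignment(score, path, coverage, interval, match_map)


@dataclass(frozen=True)
class GumbelCalibration:
    mu: float
    lam: float  # 1 / scale
    n_shuffles: int
    length: int

    def log_survival(self, score: float) -> float:
        """ln P(S >= score) under the fitted Gumbel, numerically stable."""
        z = self.lam * (score - self.mu)
        if z > 700.0:  # exp(-z) underflows; use the exact asymptote
            return -z
        t = math.exp(-z)
        p = -math.expm1(-t)
        return math.log(p) if p > 0 else -z

    def e_value(self, score: float, n_database: int) -> float:
        return n_database * math.exp(self.log_survival(score))


def calibrate_evalue(
    model: ProfileHMM,
    n_shuffles: int = 200,
    length: int | None = None,
    seed: int = 0,
) -> GumbelCalibration:
    """Fit Gumbel location/scale to forward scores of background sequences.

    The simulated null sequences are drawn i.i.d. from the model background;
    ``length`` defaults to the number of match states (a stand-in for the mean
    seed-sequence length when seeds are not at hand).
    """
    if n_shuffles < 50:
        raise CalibrationError("need at least 50 shuffles for a stable fit")
    if length is None:
        length = model.n_match_states
    rng = np.random.default_rng(seed)
    bg = model.background
    scores = np.empty(n_shuffles)
    for s in range(n_shuffles):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=bg))
        scores[s] = forward_score(model, SequenceRecord(f"shuffle{s}", seq))
    if np.std(scores) < 1e-12:
        raise CalibrationError("degenerate calibration: zero variance in null scores")
    loc, scale = stats.gumbel_r.fit(scores)
    return GumbelCalibration(mu=float(loc), lam=1.0 / float(scale),
                             n_shuffles=n_shuffles, length=length)


def filter_hits(
    hits: list[ScanHit],
    e_max: float = 1e-130,
    cov_min: float = 0.5,
    whitelist: set[str] | None = None,
) -> list[ScanHit]:
    """Apply the screening thresholds: E-value strictly below ``e_max`` AND
    model coverage strictly above ``cov_min``.  Whitelisted query ids bypass
    the filter (e.g. candidates with independent gene-cluster evidence)."""
    keep = [
        h for h in hits
        if (whitelist and h.query_id in whitelist)
        or (h.e_value < e_max and h.model_coverage > cov_min)
    ]
    return sorted(keep, key=lambda h: (h.e_value, -h.bit_score, h.query_id))


def scan_proteome(
    model: ProfileHMM,
    queries: list[SequenceRecord],
    calibration: GumbelCalibration,
    e_max: float = 1e-130,
    cov_min: float = 0.5,
    n_database: int | None = None,
    whitelist: set[str] | None = None,
) -> list[ScanHit]:
    """Score every query and return hits passing the E-value/coverage filter.

    ``n_database`` (the E-value scaling N) defaults to the number of queries.
    """
    if not queries:
        return []
    n_db = len(queries) if n_database is None else n_database
    hits = []
    for q in queries:
        score = forward_score(model, q)
        aln = viterbi_align(model, q)
        hits.append(ScanHit(
            query_id=q.id,
            bit_score=score,
            e_value=calibration.e_value(score, n_db),
            model_coverage=aln.model_coverage,
            aligned_interval=aln.aligned_interval,
        ))
    return filter_hits(hits, e_max=e_max, cov_min=cov_min, whitelist=whitelist)
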
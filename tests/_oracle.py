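"""Independent exhaustive-enumeration oracle for profile-HMM scoring.

Enumerates every local state path (entry at any match state with uniform
probability 1/L, exit at any match state) over a query substring, summing
and maximizing the odds-ratio path weights directly in linear space.  Kept
deliberately recursive and array-free so it shares no code path with the
vectorized dynamic programming it checks.
"""

from halomotif.profile_hmm import ProfileHMM, encode


def enumerate_path_odds(model: ProfileHMM, residues: str) -> tuple[float, float]:
    """Return (sum, max) of odds weights over all local alignments."""
    x = encode(residues)
    n, L = len(x), model.n_match_states
    bg = model.background
    me, ie = model.match_emissions, model.insert_emissions

    def m_odds(l, i):
        return me[l][x[i]] / bg[x[i]] if x[i] >= 0 else 1.0

    def i_odds(l, i):
        return ie[l][x[i]] / bg[x[i]] if x[i] >= 0 else 1.0

    trans = {
        "M": (model.t_mm, model.t_mi, model.t_md),
        "I": (model.t_im, model.t_ii, model.t_id),
        "D": (model.t_dm, model.t_di, model.t_dd),
    }
    total, best = 0.0, 0.0

    def recurse(state, l, i, odds):
        nonlocal total, best
        if state == "M":  # every match state is a legal exit point
            total += odds
            best = max(best, odds)
        tm, ti, td = trans[state]
        if l + 1 <= L - 1 and i < n:
            recurse("M", l + 1, i + 1, odds * tm[l] * m_odds(l + 1, i))
        if i < n:
            recurse("I", l, i + 1, odds * ti[l] * i_odds(l, i))
        if l + 1 <= L - 1:
            recurse("D", l + 1, i, odds * td[l])

    for i0 in range(n):
        for j in range(L):
            recurse("M", j, i0 + 1, (1.0 / L) * m_odds(j, i0))
    return total, best
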
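"""Numba kernels for the banded inside-outside and ratio recursions.

All kernels work in the log domain on banded ``(gap, span)`` arrays: entry
``A[i, d]`` holds the value for the gap span ``(i, i + d)``, ``0 <= d <= W``.
Sums of Boltzmann terms use log-sum-exp throughout; zero ensemble weight is
``-inf``.  Grammar states:

``Stem(i,j)``     pair (i+1, j) formed, substructure inside it
``StemEnd(i,j)``  interior of a closing pair (i, j+1): hairpin, internal
                  loop + inner Stem, or multiloop contents
``Multi(i,j)``    multiloop contents, >= 2 branches, leading unpaired
``MultiBif(i,j)`` split point: Multi1 (left, first branch flush) x Multi2
``Multi1(i,j)``   >= 1 branch starting exactly at residue i+1
``Multi2(i,j)``   exactly one branch at residue i+1, trailing unpaired
``Outer(j)``      exterior loop up to gap j (1-D; handled by the ratio
                  recursions, never materialised at N scale)

The decomposition is unambiguous: every span-constrained structure has
exactly one derivation, which the enumeration-oracle equality of Z verifies.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True, inline="always")
def _lse(a, b):
    """log(exp(a) + exp(b)) with -inf handled."""
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def inside_kernel(code, W, pt_tab, stack_lw, hairpin_lw, bulge_lw, internal_lw,
                  ml_close, ml_branch, ml_unpaired, max_internal):
    """Banded inside pass; returns (Stem, StemEnd, Multi, MultiBif, Multi1, Multi2)."""
    N = code.shape[0] - 1
    shape = (N + 1, W + 1)
    S = np.full(shape, NEG_INF)
    SE = np.full(shape, NEG_INF)
    M = np.full(shape, NEG_INF)
    MB = np.full(shape, NEG_INF)
    M1 = np.full(shape, NEG_INF)
    M2 = np.full(shape, NEG_INF)
    for d in range(0, W + 1):
        for i in range(0, N - d + 1):
            j = i + d
            # Stem: pair (i+1, j); residue span j-i in [5, W]
            if d >= 5:
                pt = pt_tab[code[i + 1], code[j]]
                if pt > 0:
                    acc = SE[i + 1, d - 2]
                    if d - 2 >= 5:
                        pt_in = pt_tab[code[i + 2], code[j - 1]]
                        if pt_in > 0 and S[i + 1, d - 2] != NEG_INF:
                            acc = _lse(acc, stack_lw[pt, pt_in] + S[i + 1, d - 2])
                    S[i, d] = acc
            # Multi2: one branch flush left, trailing unpaired
            if d >= 5:
                acc = NEG_INF
                if S[i, d] != NEG_INF:
                    acc = S[i, d] + ml_branch
                if d >= 1 and M2[i, d - 1] != NEG_INF:
                    acc = _lse(acc, M2[i, d - 1] + ml_unpaired)
                M2[i, d] = acc
            # MultiBif: Multi1(i,k) . Multi2(k,j)
            if d >= 10:
                acc = NEG_INF
                for k in range(i + 5, j - 4):
                    a1 = M1[i, k - i]
                    if a1 == NEG_INF:
                        continue
                    a2 = M2[k, j - k]
                    if a2 != NEG_INF:
                        acc = _lse(acc, a1 + a2)
                MB[i, d] = acc
            # Multi1: Multi2 | MultiBif
            if d >= 5:
                M1[i, d] = _lse(M2[i, d], MB[i, d])
            # Multi: leading unpaired | MultiBif
            if d >= 10:
                acc = MB[i, d]
                if M[i + 1, d - 1] != NEG_INF:
                    acc = _lse(acc, M[i + 1, d - 1] + ml_unpaired)
                M[i, d] = acc
            # StemEnd: interior of closing pair (i, j+1)
            if 3 <= d <= W - 2 and j + 1 <= N and i >= 1:
                pt_close = pt_tab[code[i], code[j + 1]]
                if pt_close > 0:
                    acc = hairpin_lw[d]
                    # internal loops / bulges around an inner Stem(p, q)
                    lmax = min(max_internal, d - 5)
                    for li in range(0, lmax + 1):
                        p = i + li
                        rmax = min(max_internal - li, d - li - 5)
                        for rj in range(0, rmax + 1):
                            if li == 0 and rj == 0:
                                continue  # pure stack handled in Stem
                            q = j - rj
                            sv = S[p, q - p]
                            if sv == NEG_INF:
                                continue
                            if li == 0 or rj == 0:
                                acc = _lse(acc, bulge_lw[li + rj] + sv)
                            else:
                                acc = _lse(acc, internal_lw[li + rj] + sv)
                    if M[i, d] != NEG_INF:
                        acc = _lse(acc, M[i, d] + ml_close)
                    SE[i, d] = acc
    return S, SE, M, MB, M1, M2


@njit(cache=True)
def outer_raw_kernel(code, W, pt_tab, S, ext_pair_lw):
    """Raw log alpha_Outer / beta_Outer accumulation (reference path)."""
    N = code.shape[0] - 1
    la = np.full(N + 1, NEG_INF)
    lb = np.full(N + 1, NEG_INF)
    la[0] = 0.0
    for j in range(1, N + 1):
        acc = la[j - 1]
        for p in range(max(0, j - W), j - 4):
            sv = S[p, j - p]
            if sv != NEG_INF:
                pt = pt_tab[code[p + 1], code[j]]
                acc = _lse(acc, la[p] + ext_pair_lw[pt] + sv)
        la[j] = acc
    lb[N] = 0.0
    for i in range(N - 1, -1, -1):
        acc = lb[i + 1]
        for q in range(i + 5, min(N, i + W) + 1):
            sv = S[i, q - i]
            if sv != NEG_INF:
                pt = pt_tab[code[i + 1], code[q]]
                acc = _lse(acc, ext_pair_lw[pt] + sv + lb[q])
        lb[i] = acc
    return la, lb


@njit(cache=True)
def delta_alpha_kernel(code, W, pt_tab, S, ext_pair_lw):
    """Direct-ratio recursion for log dalpha(h) = log alpha(h+1)/alpha(h)."""
    N = code.shape[0] - 1
    dal = np.empty(N)
    for j in range(1, N + 1):
        acc = 0.0  # unpaired step, t(Outer->Outer) = 1
        back = 0.0
        for p in range(j - 2, max(0, j - W) - 1, -1):
            back -= dal[p]  # back = log alpha(p) - log alpha(j-1)
            if j - p < 5:
                continue
            sv = S[p, j - p]
            if sv != NEG_INF:
                pt = pt_tab[code[p + 1], code[j]]
                acc = _lse(acc, back + ext_pair_lw[pt] + sv)
        dal[j - 1] = acc
    return dal


@njit(cache=True)
def delta_beta_kernel(code, W, pt_tab, S, ext_pair_lw):
    """Mirrored recursion for log dbeta(h) = log beta(h)/beta(h+1)."""
    N = code.shape[0] - 1
    dbe = np.empty(N)
    for i in range(N - 1, -1, -1):
        acc = 0.0
        fwd = 0.0
        for q in range(i + 2, min(N, i + W) + 1):
            fwd -= dbe[q - 1]  # fwd = log beta(q) - log beta(i+1)
            if q - i < 5:
                continue
            sv = S[i, q - i]
            if sv != NEG_INF:
                pt = pt_tab[code[i + 1], code[q]]
                acc = _lse(acc, ext_pair_lw[pt] + sv + fwd)
        dbe[i] = acc
    return dbe


@njit(cache=True)
def rho_kernel(code, W, pt_tab, S, ext_pair_lw, dal, dbe):
    """log rho(i) = log Z/(alpha_Outer(i) beta_Outer(i)) via the anchor sum.

    Anchored at i: every structure either leaves residue i+1 exterior-unpaired
    or covers it with an outermost pair (p, q), p <= i < q.
    """
    N = code.shape[0] - 1
    rho = np.zeros(N + 1)
    for i in range(1, N):
        acc = -dbe[i]  # unpaired step (i, i+1)
        aterm = 0.0  # log alpha(p)/alpha(i)
        for p in range(i, max(0, i - W + 1) - 1, -1):
            if p < i:
                aterm -= dal[p]
            bterm = 0.0  # log beta(q)/beta(i)
            for q in range(i + 1, min(N, p + W) + 1):
                bterm -= dbe[q - 1]
                if q - p < 5:
                    continue
                sv = S[p, q - p]
                if sv != NEG_INF:
                    pt = pt_tab[code[p + 1], code[q]]
                    acc = _lse(acc, aterm + ext_pair_lw[pt] + sv + bterm)
        rho[i] = acc
    return rho


@njit(cache=True)
def logr_kernel(code, W, pt_tab, S, rho, dbe):
    """log r(i,j) = log rho(i) + sum_{h=i}^{j-1} log dbeta(h), banded.

    Filled for every (i, j) with j - i <= W (the simplified dynamic range);
    entries outside P are still valid r values but unused by the engine.
    """
    N = code.shape[0] - 1
    logr = np.full((N + 1, W + 1), np.nan)
    for i in range(0, N + 1):
        acc = rho[i]
        logr[i, 0] = acc
        for d in range(1, min(W, N - i) + 1):
            acc += dbe[i + d - 1]
            logr[i, d] = acc
    return logr


@njit(cache=True)
def outside_kernel(code, W, pt_tab, S, SE, M, MB, M1, M2, logr,
                   stack_lw, hairpin_lw, bulge_lw, internal_lw,
                   ml_close, ml_branch, ml_unpaired, max_internal, ext_pair_lw):
    """Banded outside pass on probability scale: B*[i,d] = log beta_state/Z.

    The exterior context enters through ``-log r(i,j)`` at Stem cells; all
    other contributions propagate inside windows of span <= W.
    """
    N = code.shape[0] - 1
    shape = (N + 1, W + 1)
    BS = np.full(shape, NEG_INF)
    BSE = np.full(shape, NEG_INF)
    BM = np.full(shape, NEG_INF)
    BMB = np.full(shape, NEG_INF)
    BM1 = np.full(shape, NEG_INF)
    BM2 = np.full(shape, NEG_INF)
    for d in range(W, -1, -1):
        for i in range(0, N - d + 1):
            j = i + d
            # StemEnd <- Stem(i-1, j+1)
            if SE[i, d] != NEG_INF:
                BSE[i, d] = BS[i - 1, d + 2] if (i >= 1 and d + 2 <= W) else NEG_INF
            # Multi <- StemEnd (multiloop closing) | Multi(i-1, j) leading unpaired
            if M[i, d] != NEG_INF:
                acc = NEG_INF
                if BSE[i, d] != NEG_INF:
                    acc = BSE[i, d] + ml_close
                if i >= 1 and d + 1 <= W and BM[i - 1, d + 1] != NEG_INF:
                    acc = _lse(acc, BM[i - 1, d + 1] + ml_unpaired)
                BM[i, d] = acc
            # Multi1 <- MultiBif(i, j') splits, j' > j
            if M1[i, d] != NEG_INF:
                acc = NEG_INF
                for dd in range(d + 5, min(W, N - i) + 1):
                    bmb = BMB[i, dd]
                    if bmb == NEG_INF:
                        continue
                    a2 = M2[j, i + dd - j]
                    if a2 != NEG_INF:
                        acc = _lse(acc, bmb + a2)
                BM1[i, d] = acc
            # MultiBif <- Multi (same span) | Multi1 (same span)
            if MB[i, d] != NEG_INF:
                BMB[i, d] = _lse(BM[i, d], BM1[i, d])
            # Multi2 <- MultiBif(p, j) with Multi1(p, i), p < i
            #         | Multi1 (same span) | Multi2(i, j+1) trailing unpaired
            if M2[i, d] != NEG_INF:
                acc = BM1[i, d]
                if d + 1 <= W and j + 1 <= N and BM2[i, d + 1] != NEG_INF:
                    acc = _lse(acc, BM2[i, d + 1] + ml_unpaired)
                for p in range(max(0, j - W), i - 4):
                    bmb = BMB[p, j - p]
                    if bmb == NEG_INF:
                        continue
                    a1 = M1[p, i - p]
                    if a1 != NEG_INF:
                        acc = _lse(acc, bmb + a1)
                BM2[i, d] = acc
            # Stem <- exterior | stack | internal loop of an enclosing
            #         StemEnd | Multi2 branch
            if S[i, d] != NEG_INF:
                acc = NEG_INF
                pt = pt_tab[code[i + 1], code[j]]
                lr = logr[i, d]
                if not np.isnan(lr):
                    acc = ext_pair_lw[pt] - lr
                if i >= 1 and d + 2 <= W and j + 1 <= N and BS[i - 1, d + 2] != NEG_INF:
                    pt_out = pt_tab[code[i], code[j + 1]]
                    if pt_out > 0:
                        acc = _lse(acc, BS[i - 1, d + 2] + stack_lw[pt_out, pt])
                # enclosing StemEnd(k, l), loop sizes (i-k, l-j) not both 0
                for li in range(0, max_internal + 1):
                    k = i - li
                    if k < 1:
                        break
                    dmax = min(W - 2, d + li + (max_internal - li))
                    for dl in range(d + li, dmax + 1):
                        if li == 0 and dl == d:
                            continue
                        l = k + dl
                        if l > N - 1:
                            break
                        bse = BSE[k, dl]
                        if bse == NEG_INF:
                            continue
                        rj = l - j
                        if li == 0 or rj == 0:
                            acc = _lse(acc, bse + bulge_lw[li + rj])
                        else:
                            acc = _lse(acc, bse + internal_lw[li + rj])
                if BM2[i, d] != NEG_INF:
                    acc = _lse(acc, BM2[i, d] + ml_branch)
                BS[i, d] = acc
    return BS, BSE, BM, BMB, BM1, BM2


@njit(cache=True)
def bpp_kernel(S, BS):
    """p(i+1, j) = exp(alpha_Stem(i,j) + log beta_Stem(i,j)/Z), banded."""
    N1, W1 = S.shape
    p = np.zeros((N1, W1))
    for i in range(N1):
        for d in range(W1):
            if S[i, d] != NEG_INF and BS[i, d] != NEG_INF:
                p[i, d] = np.exp(S[i, d] + BS[i, d])
    return p


@njit(cache=True)
def profile_kernel(code, W, pt_tab, S, SE, M, MB, M1, M2,
                   BS, BSE, BM, BMB, BM1, BM2,
                   hairpin_lw, bulge_lw, internal_lw,
                   ml_close, ml_branch, ml_unpaired, max_internal,
                   rho, dbe):
    """Per-position loop-type occupancy from transition probabilities.

    Returns (hairpin, bulge, interior, multi, exterior) arrays of length N+1
    (1-based positions).  Unpaired residues are attributed to the loop of the
    transition that emits them; range contributions use difference arrays.
    """
    N = code.shape[0] - 1
    hair = np.zeros(N + 2)
    bulge = np.zeros(N + 2)
    inter = np.zeros(N + 2)
    multi = np.zeros(N + 2)
    exter = np.zeros(N + 2)
    for d in range(3, W - 1):
        for i in range(1, N - d):
            j = i + d
            bse = BSE[i, d]
            if bse == NEG_INF:
                continue
            # hairpin emission: residues i+1..j unpaired
            if hairpin_lw[d] != NEG_INF:
                pr = np.exp(bse + hairpin_lw[d])
                hair[i + 1] += pr
                hair[j + 1] -= pr
            # internal/bulge: StemEnd(i,j) -> Stem(p,q)
            lmax = min(max_internal, d - 5)
            for li in range(0, lmax + 1):
                p = i + li
                rmax = min(max_internal - li, d - li - 5)
                for rj in range(0, rmax + 1):
                    if li == 0 and rj == 0:
                        continue
                    q = j - rj
                    sv = S[p, q - p]
                    if sv == NEG_INF:
                        continue
                    lw = bulge_lw[li + rj] if (li == 0 or rj == 0) else internal_lw[li + rj]
                    pr = np.exp(bse + lw + sv)
                    if li == 0 or rj == 0:
                        bulge[i + 1] += pr
                        bulge[p + 1] -= pr
                        bulge[q + 1] += pr
                        bulge[j + 1] -= pr
                    else:
                        inter[i + 1] += pr
                        inter[p + 1] -= pr
                        inter[q + 1] += pr
                        inter[j + 1] -= pr
    # multiloop unpaired emissions
    for d in range(0, W + 1):
        for i in range(0, N - d + 1):
            j = i + d
            # Multi(i,j) -> Multi(i+1,j): residue i+1 unpaired in multi
            if d >= 1 and BM[i, d] != NEG_INF and M[i + 1, d - 1] != NEG_INF:
                multi[i + 1] += np.exp(BM[i, d] + ml_unpaired + M[i + 1, d - 1])
            # Multi2(i,j) -> Multi2(i,j-1): residue j unpaired in multi
            if d >= 1 and BM2[i, d] != NEG_INF and M2[i, d - 1] != NEG_INF:
                multi[j] += np.exp(BM2[i, d] + ml_unpaired + M2[i, d - 1])
    # exterior: p_ext(t) = alpha(t-1) beta(t) / Z = exp(-rho(t-1) - dbeta(t-1))
    for t in range(1, N + 1):
        exter[t] = np.exp(-rho[t - 1] - dbe[t - 1])
    h = np.cumsum(hair)[1 : N + 1]
    b = np.cumsum(bulge)[1 : N + 1]
    it = np.cumsum(inter)[1 : N + 1]
    return h, b, it, multi[1 : N + 1], exter[1 : N + 1]


@njit(cache=True)
def stem_kernel(p_band):
    """p_stem(t) = sum_j p(t, j) + sum_j p(j, t) from the banded bpp."""
    N1, W1 = p_band.shape
    N = N1 - 1
    out = np.zeros(N)
    for i in range(N1):
        for d in range(5, W1):
            pr = p_band[i, d]
            if pr > 0.0:
                out[i] += pr  # residue i+1 (1-based) -> index i
                out[i + d - 1] += pr  # residue i+d
    return out


@njit(cache=True)
def alpha_chain_kernel(code, W, pt_tab, S, ext_pair_lw, s, e, H):
    """Forward segment chains: coefficients of alpha_Outer(s-h) in alpha_Outer(k).

    ``code``/``S`` live in slice coordinates (gap 0 = global gap ``lo``);
    ``s``/``e`` are the segment's gap range in slice coordinates.  Returns
    ``ch[h, k - s]`` (log) for k = s..e.
    """
    n = code.shape[0] - 1
    ch = np.full((H, n + 1), NEG_INF)
    for h in range(H):
        ch[h, s - h] = 0.0
    for k in range(s + 1, e + 1):
        for h in range(H):
            acc = ch[h, k - 1]
            for p in range(max(s - H + 1, k - W), k - 4):
                sv = S[p, k - p]
                if sv != NEG_INF and ch[h, p] != NEG_INF:
                    pt = pt_tab[code[p + 1], code[k]]
                    acc = _lse(acc, ch[h, p] + ext_pair_lw[pt] + sv)
            ch[h, k] = acc
    return ch[:, s : e + 1]


@njit(cache=True)
def beta_chain_kernel(code, W, pt_tab, S, ext_pair_lw, s, e, H):
    """Backward segment chains: coefficients of beta_Outer(e+h) in beta_Outer(k)."""
    n = code.shape[0] - 1
    ch = np.full((H, n + 1), NEG_INF)
    for h in range(H):
        ch[h, e + h] = 0.0
    for k in range(e - 1, s - 1, -1):
        for h in range(H):
            acc = ch[h, k + 1]
            for q in range(k + 5, min(e + H - 1, k + W) + 1):
                sv = S[k, q - k]
                if sv != NEG_INF and ch[h, q] != NEG_INF:
                    pt = pt_tab[code[k + 1], code[q]]
                    acc = _lse(acc, ext_pair_lw[pt] + sv + ch[h, q])
            ch[h, k] = acc
    return ch[:, s : e + 1]
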
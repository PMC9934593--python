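"""Independent reference implementations used only as test oracles.

Deliberately naive: plain-Python dynamic programming and exhaustive
enumeration, coded separately from the package's implementations so the two
routes can disagree.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_affine_oracle(query: str, subject: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Brute-force affine-gap local alignment (full Gotoh DP, dict-based).

    Same documented objective as the package aligner: lexicographic
    maximisation of (score, matches, -gap columns, -mismatches), within-cell
    preference substitution > gap-in-subject > gap-in-query and opening over
    extension, alignment ending at the first maximum in row-major order.
    Returns (score, identity %, coverage %, aligned_length).
    """
    q, s = query.upper(), subject.upper()
    n, m = len(q), len(s)
    ZERO = (0, 0, 0, 0)
    BOTTOM = (NEG, 0, 0, 0)
    H = {}
    E = {}
    F = {}
    pH = {}
    pE = {}
    pF = {}

    def plus(v, dscore, dmatch=0, dgap=0, dmis=0):
        return (v[0] + dscore, v[1] + dmatch, v[2] + dgap, v[3] + dmis)

    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 or j == 0:
                H[i, j] = ZERO
                E[i, j] = BOTTOM
                F[i, j] = BOTTOM
                pH[i, j] = None
                continue
            fo = plus(H[i - 1, j], gap_open, dgap=-1)
            fe = plus(F[i - 1, j], gap_extend, dgap=-1)
            F[i, j], pF[i, j] = (fo, "open") if fo >= fe else (fe, "ext")
            eo = plus(H[i, j - 1], gap_open, dgap=-1)
            ee = plus(E[i, j - 1], gap_extend, dgap=-1)
            E[i, j], pE[i, j] = (eo, "open") if eo >= ee else (ee, "ext")
            if q[i - 1] == s[j - 1]:
                d = plus(H[i - 1, j - 1], match, dmatch=1)
            else:
                d = plus(H[i - 1, j - 1], mismatch, dmis=-1)
            val, ptr = d, "diag"
            if F[i, j] > val:
                val, ptr = F[i, j], "up"
            if E[i, j] > val:
                val, ptr = E[i, j], "left"
            if val[0] <= 0:
                H[i, j], pH[i, j] = ZERO, None
            else:
                H[i, j], pH[i, j] = val, ptr
    best, bi, bj = ZERO, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    best = best[0]
    if best <= 0:
        return 0, 0.0, 0.0, 0
    i, j = bi, bj
    state = "H"
    matches = aligned = subj_cols = 0
    while True:
        if state == "H":
            ptr = pH[i, j]
            if ptr is None:
                break
            if ptr == "diag":
                aligned += 1
                subj_cols += 1
                matches += q[i - 1] == s[j - 1]
                i, j = i - 1, j - 1
            elif ptr == "up":
                state = "F"
            else:
                state = "E"
        elif state == "F":
            aligned += 1
            back = pF[i, j]
            i -= 1
            if back == "open":
                state = "H"
        else:
            aligned += 1
            subj_cols += 1
            back = pE[i, j]
            j -= 1
            if back == "open":
                state = "H"
    return best, 100.0 * matches / aligned, 100.0 * subj_cols / m, aligned


def demux_oracle(read2, scheme, pool_barcode_ids, barcode_mm=1, primer_mm=2):
    """Exhaustive enumeration of every (spacer length, barcode) assignment.

    Returns the winning barcode id, or the strings "ambiguous"/"none" —
    without distinguishing the package's unassigned reason codes.
    """
    from mycobarcode._dna import IUPAC

    primer = scheme.reverse_primer
    seq = read2.upper()
    candidates = []
    for s in range(0, 5):
        bc_obs = seq[s : s + 5]
        pr_obs = seq[s + 5 : s + 5 + len(primer)]
        if len(bc_obs) < 5 or len(pr_obs) < len(primer):
            continue
        for bc_id in pool_barcode_ids:
            bc = scheme.barcode(bc_id)
            d_bc = sum(a != b for a, b in zip(bc_obs, bc))
            d_pr = sum(o not in IUPAC[p] for o, p in zip(pr_obs, primer))
            if d_bc <= barcode_mm and d_pr <= primer_mm:
                candidates.append((d_bc + d_pr, s, bc_id))
    if not candidates:
        return "none"
    best = min(c[0] for c in candidates)
    winners = {bc for tot, s, bc in candidates if tot == best}
    if len(winners) > 1:
        return "ambiguous"
    return winners.pop()
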
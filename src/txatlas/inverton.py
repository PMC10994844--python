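"""Genome-wide inverted-repeat (inverton) discovery.

An inverted repeat is a pair of arms where the right arm is the reverse
complement of the left arm up to a length-dependent mismatch budget:
no mismatches for arms of at most 11 bp, one mismatch for arms of 12-19 bp
and two mismatches for arms longer than 19 bp. (The budget for 14-19 bp is
interpolated between the stated 13-bp and >19-bp anchors.)

The scan is exhaustive: every base pairing (x, y) of an inverted repeat
satisfies x + y = const, so candidate arms are windows along the
anti-diagonals of the sequence self-comparison, which the scanner sweeps
with cumulative sums (vectorized across diagonals). This enumerates every
(arm, spacer) geometry within the configured ranges — no seeding
heuristics — and then suppresses non-maximal hits: a hit is dropped when
both of its arms are contained in another hit's arms that has at most the
same number of mismatches.

Filters follow common inverton-scanner practice: homopolymeric arms are
removed and the GC fraction over both arms must fall within [0.15, 0.85].
A hit is promoter-associated when its arms-plus-spacer span intersects the
50-bp window upstream of a mapped TSS (strand-aware by default).
"""

from __future__ import annotations

import numpy as np

from .models import InvertedRepeat, TSSRecord

DEFAULT_ARM_MIN = 5
DEFAULT_ARM_MAX = 25
DEFAULT_SPACER_MIN = 30
DEFAULT_SPACER_MAX = 1000
DEFAULT_GC_MIN = 0.15
DEFAULT_GC_MAX = 0.85
DEFAULT_PROMOTER_WINDOW = 50

_ENC = np.full(128, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def mismatch_budget(arm_length: int) -> int:
    """Length-dependent mismatch budget: 0 for <=11 bp, 1 for 12-19 bp,
    2 for >19 bp."""
    if arm_length <= 11:
        return 0
    if arm_length <= 19:
        return 1
    return 2


def _encode(sequence: str) -> np.ndarray:
    codes = _ENC[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence must contain only A/C/G/T")
    return codes


def find_inverted_repeats(
    sequence: str,
    arm_min: int = DEFAULT_ARM_MIN,
    arm_max: int = DEFAULT_ARM_MAX,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    replicon: str = "replicon1",
    chunk: int = 4096,
) -> list[InvertedRepeat]:
    """All maximal inverted-repeat arm pairs within the given ranges."""
    if arm_min < 5:
        raise ValueError("arm_min must be >= 5")
    if arm_max < arm_min:
        raise ValueError("arm_max must be >= arm_min")
    if spacer_min < 0 or spacer_max < spacer_min:
        raise ValueError("invalid spacer range")
    n = len(sequence)
    if n < 2 * arm_min + spacer_min:
        return []
    codes = _encode(sequence)
    comp = _COMP[codes]

    # innermost-gap parameterization along anti-diagonals c = x + y:
    # left index x = x0(c) - t, right index y = c - x; spacer(t_in) =
    # (c - 1 - 2 * x0) + 2 * t_in for the innermost arm position t_in.
    width = arm_max + spacer_max // 2 + 1
    raw: list[tuple[int, int, int, int]] = []  # (a0, L, spacer, mismatches)
    c_all = np.arange(2 * arm_min + spacer_min - 1, 2 * n - 2 - (2 * arm_min + spacer_min - 1) + 1)
    t = np.arange(width)
    for lo in range(0, len(c_all), chunk):
        c = c_all[lo : lo + chunk][:, None]
        x0 = (c - 1) // 2
        g0 = c - 1 - 2 * x0  # 0 or 1
        X = x0 - t[None, :]
        Y = c - X
        valid = (X >= 0) & (Y < n)
        Xc = np.clip(X, 0, n - 1)
        Yc = np.clip(Y, 0, n - 1)
        match = valid & (codes[Xc] == comp[Yc])
        cm = np.zeros((match.shape[0], width + 1), dtype=np.int32)
        np.cumsum(match, axis=1, out=cm[:, 1:])
        cv = np.zeros_like(cm)
        np.cumsum(valid, axis=1, out=cv[:, 1:])
        for L in range(arm_min, arm_max + 1):
            budget = mismatch_budget(L)
            m = cm[:, L:] - cm[:, :-L]  # matches for windows [t_in, t_in+L)
            v = cv[:, L:] - cv[:, :-L]
            t_in = np.arange(width - L + 1)[None, :]
            spacer = g0 + 2 * t_in
            ok = (
                (v == L)
                & (L - m <= budget)
                & (spacer >= spacer_min)
                & (spacer <= spacer_max)
            )
            rows, cols = np.nonzero(ok)
            if rows.size:
                cc = c[rows, 0]
                tt = cols
                x_in = (cc - 1) // 2 - tt
                a0 = x_in - L + 1
                sp = g0[rows, 0] + 2 * tt
                mm = L - m[rows, cols]
                raw.extend(zip(a0.tolist(), [L] * len(rows), sp.tolist(), mm.tolist()))
    hits = _suppress_contained(raw)
    out = []
    for a0, L, spacer, mm in hits:
        left = sequence[a0 : a0 + L].upper()
        right_start0 = a0 + L + spacer
        right = sequence[right_start0 : right_start0 + L].upper()
        both = left + right
        gc = (both.count("G") + both.count("C")) / len(both)
        out.append(
            InvertedRepeat(
                replicon=replicon,
                left_start=a0 + 1,
                left_end=a0 + L,
                right_start=right_start0 + 1,
                right_end=right_start0 + L,
                mismatches=int(mm),
                gc_fraction=gc,
                homopolymeric=(len(set(left)) == 1 and len(set(right)) == 1),
            )
        )
    out.sort(key=lambda ir: (ir.left_start, ir.right_end))
    return out


def _suppress_contained(raw: list[tuple[int, int, int, int]]):
    """Drop hits whose both arms lie inside another hit's arms with <= its
    mismatch count."""
    if not raw:
        return []
    arr = np.array(sorted(set(raw)), dtype=np.int64)
    a0, L, sp, mm = arr.T
    le = a0 + L - 1  # left arm [a0, le]
    rs = a0 + L + sp
    re = rs + L - 1  # right arm [rs, re]
    keep = np.ones(len(arr), dtype=bool)
    for i in range(len(arr)):
        contains = (
            (a0 <= a0[i]) & (le >= le[i]) & (rs <= rs[i]) & (re >= re[i]) & (mm <= mm[i])
        )
        contains[i] = False
        if contains.any():
            keep[i] = False
    return [tuple(int(v) for v in arr[i]) for i in np.flatnonzero(keep)]


def filter_inverted_repeats(
    hits: list[InvertedRepeat],
    gc_min: float = DEFAULT_GC_MIN,
    gc_max: float = DEFAULT_GC_MAX,
    remove_homopolymeric: bool = True,
) -> list[InvertedRepeat]:
    """Remove homopolymeric arms and out-of-range GC fractions."""
    out = []
    for ir in hits:
        if remove_homopolymeric and ir.homopolymeric:
            continue
        if not (gc_min <= ir.gc_fraction <= gc_max):
            continue
        out.append(ir)
    return out


def flag_promoter_invertons(
    hits: list[InvertedRepeat],
    tss_records: list[TSSRecord],
    window: int = DEFAULT_PROMOTER_WINDOW,
    strand_aware: bool = True,
) -> list[InvertedRepeat]:
    """Set ``promoter_flag`` when the arms-plus-spacer span intersects the
    ``window``-bp region upstream of any mapped TSS."""
    for ir in hits:
        ir.promoter_flag = False
        ir.supporting_tss = []
        for r in tss_records:
            if r.replicon != ir.replicon:
                continue
            windows = []
            if strand_aware:
                if r.strand == "+":
                    windows.append((r.position - window, r.position - 1))
                else:
                    windows.append((r.position + 1, r.position + window))
            else:
                windows.append((r.position - window, r.position - 1))
                windows.append((r.position + 1, r.position + window))
            for lo, hi in windows:
                if lo <= ir.right_end and ir.left_start <= hi:
                    ir.promoter_flag = True
                    ir.supporting_tss.append(r.position)
                    break
    return hits


def brute_force_inverted_repeats(
    sequence: str,
    arm_min: int = DEFAULT_ARM_MIN,
    arm_max: int = DEFAULT_ARM_MAX,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    replicon: str = "replicon1",
) -> list[InvertedRepeat]:
    """Independent enumeration used for cross-checking the scanner.

    Slides fixed (arm length, spacer) window pairs over the sequence and
    counts mismatches against the reverse complement directly — a different
    decomposition of the same exhaustive search.
    """
    n = len(sequence)
    codes = _encode(sequence)
    comp = _COMP[codes]
    raw: list[tuple[int, int, int, int]] = []
    for L in range(arm_min, min(arm_max, (n - spacer_min) // 2) + 1):
        budget = mismatch_budget(L)
        if n - L + 1 <= 0:
            continue
        left = np.lib.stride_tricks.sliding_window_view(codes, L)
        right_rc = np.lib.stride_tricks.sliding_window_view(comp, L)[:, ::-1]
        for spacer in range(spacer_min, spacer_max + 1):
            shift = L + spacer
            if shift + L > n:
                break
            mism = (left[: n - 2 * L - spacer + 1] != right_rc[shift:]).sum(axis=1)
            for a0 in np.flatnonzero(mism <= budget):
                raw.append((int(a0), L, spacer, int(mism[a0])))
    hits = _suppress_contained(raw)
    out = []
    for a0, L, spacer, mm in hits:
        left_s = sequence[a0 : a0 + L].upper()
        rs0 = a0 + L + spacer
        right_s = sequence[rs0 : rs0 + L].upper()
        both = left_s + right_s
        out.append(
            InvertedRepeat(
                replicon=replicon,
                left_start=a0 + 1,
                left_end=a0 + L,
                right_start=rs0 + 1,
                right_end=rs0 + L,
                mismatches=mm,
                gc_fraction=(both.count("G") + both.count("C")) / len(both),
                homopolymeric=(len(set(left_s)) == 1 and len(set(right_s)) == 1),
            )
        )
    out.sort(key=lambda ir: (ir.left_start, ir.right_end))
    return out
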
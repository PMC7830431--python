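"""Independent oracles used only by the test suite.

These are deliberately naive reference implementations (full dynamic
programming, exhaustive scans) against which the package's faster
algorithms are checked on small instances.
"""
from __future__ import annotations

NEG_INF = float("-inf")


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -2, gap: int = -3):
    """Full O(nm) local alignment; returns (identity, a_interval, b_interval).

    Identity is matches / aligned columns (gap columns count in the
    denominator, matching the engine's convention on gapless instances).
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]  # 1=diag 2=up 3=left
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] and ai != "N" else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            score = max(0, diag, up, left)
            row[j] = score
            if score == diag and score > 0:
                P[i][j] = 1
            elif score == up and score > 0:
                P[i][j] = 2
            elif score == left and score > 0:
                P[i][j] = 3
            if score > best:
                best, bi, bj = score, i, j
    # traceback
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        p = P[i][j]
        columns += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        elif p == 3:
            j -= 1
        else:
            break
    identity = matches / columns if columns else 0.0
    return identity, (i, bi), (j, bj)


_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_orfs(seq: str, min_aa: int = 100, include_partial: bool = True):
    """Exhaustive six-frame ORF scan by splitting each frame at stop codons.

    Returns a set of (strand, frame, start, end, aa_length, partial) tuples
    in forward-sequence coordinates, same conventions as the ORF finder:
    one maximal ORF (first ATG) per inter-stop segment.
    """
    n = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", seq.translate(_COMP)[::-1])):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            segment_start = 0  # codon index where the current inter-stop segment begins
            for idx, codon in enumerate(codons + ["TAA_sentinel"]):
                is_stop = codon in _STOPS
                is_end = idx == len(codons)
                if not (is_stop or is_end):
                    continue
                segment = codons[segment_start:idx]
                for k, c in enumerate(segment):
                    if c == "ATG":
                        start_codon = segment_start + k
                        if is_stop:
                            start = frame + 3 * start_codon
                            end = frame + 3 * (idx + 1)
                            aa = idx - start_codon
                            partial = False
                        else:
                            start = frame + 3 * start_codon
                            end = frame + 3 * idx
                            aa = idx - start_codon
                            partial = True
                            if not include_partial:
                                break
                        if aa >= min_aa:
                            if strand == "-":
                                start, end = n - end, n - start
                            found.add((strand, frame, start, end, aa, partial))
                        break
                segment_start = idx + 1
    return found
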
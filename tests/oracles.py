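"""Independent reference implementations used as test oracles.

These re-derive results from first principles (explicit enumeration,
per-element loops, closed forms) without sharing code paths with the
package implementation.
"""

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "CTG", "GTG", "TTG"}
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def brute_force_orfs(seq: str, min_len: int = 60, all_starts: bool = False):
    """Enumerate ORF tuples (start, end, strand, completeness) by examining
    every in-frame start/stop pair directly on each of the six frames.
    """
    n = len(seq)
    found = {}

    def record(start, end, strand, comp):
        if end - start < min_len:
            return
        key = (start, end, strand)
        if key not in found or (found[key] != "complete" and comp == "complete"):
            found[key] = comp

    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)

        def fwd(a, b):
            # map coding-strand half-open interval back to forward strand
            return (a, b) if strand == "+" else (n - b, n - a)

        for frame in range(3):
            positions = list(range(frame, n - 2, 3))
            codon = {p: s[p:p + 3] for p in positions}
            stop_list = [p for p in positions if codon[p] in STOPS]
            start_list = [p for p in positions if codon[p] in STARTS]
            frame_end = positions[-1] + 3 if positions else frame

            for sp in stop_list:
                prev_stops = [q for q in stop_list if q < sp]
                floor = max(prev_stops) + 3 if prev_stops else frame
                cand = [p for p in start_list if floor <= p < sp]
                chosen = cand if all_starts else cand[:1]
                for p in chosen:
                    record(*fwd(p, sp + 3), strand, "complete")
                if not prev_stops and not (cand and cand[0] == frame):
                    # leading fragment-edge segment through the first stop
                    record(*fwd(frame, sp + 3), strand, "missing5")

            tail_floor = max(stop_list) + 3 if stop_list else frame
            tail_starts = [p for p in start_list if p >= tail_floor]
            if stop_list:
                chosen = tail_starts if all_starts else tail_starts[:1]
                for p in chosen:
                    record(*fwd(p, frame_end), strand, "missing3")
            else:
                if tail_starts:
                    chosen = tail_starts if all_starts else tail_starts[:1]
                    for p in chosen:
                        record(*fwd(p, frame_end), strand, "missing3")
                elif positions:
                    record(*fwd(frame, frame_end), strand, "missing_both")
    return {(a, b, st, comp) for (a, b, st), comp in found.items()}


def greedy_oracle(intervals, overlap_threshold=60, min_prob=0.5):
    """O(n^2) restatement of greedy overlap resolution.

    ``intervals``: list of (seq_id, start, end, strand, prob).  Returns the
    retained subset, sorted by (seq_id, start, end).
    """
    alive = [iv for iv in intervals if iv[4] >= min_prob]
    alive.sort(key=lambda iv: (-iv[4], -(iv[2] - iv[1]), iv[1], iv[3]))
    accepted = []
    for iv in alive:
        ok = True
        for acc in accepted:
            if acc[0] == iv[0]:
                ov = min(acc[2], iv[2]) - max(acc[1], iv[1])
                if ov > overlap_threshold:
                    ok = False
                    break
        if ok:
            accepted.append(iv)
    return sorted(accepted, key=lambda iv: (iv[0], iv[1], iv[2]))


def pairwise_auc(scores, labels) -> float:
    """All-pairs comparison AUC with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def direct_conv1d(x, w, b):
    """Naive direct convolution: x (C,L), w (O,C,K), b (O) -> (O, L-K+1)."""
    C, L = x.shape
    O, _, K = w.shape
    out = np.zeros((O, L - K + 1))
    for o in range(O):
        for t in range(L - K + 1):
            acc = b[o]
            for c in range(C):
                for k in range(K):
                    acc += x[c, t + k] * w[o, c, k]
            out[o, t] = acc
    return out


def reference_lstm(x, wx, wh, b):
    """Step-by-step scalar-form LSTM recurrence for one sample: x (T, D)."""
    T, D = x.shape
    H = wh.shape[0]

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    h = np.zeros(H)
    c = np.zeros(H)
    hs = []
    for t in range(T):
        z = x[t] @ wx + h @ wh + b
        i, f = sig(z[:H]), sig(z[H:2 * H])
        g, o = np.tanh(z[2 * H:3 * H]), sig(z[3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        hs.append(h.copy())
    return np.array(hs)
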
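"""Promoter extraction and ungapped motif discovery by ZOOPS EM.

Upstream regions (default 1000 bp, on the coding strand, truncated at
contig edges) are searched for shared ungapped motifs of width 6-30
with an expectation-maximization mixture model in which every promoter
contains zero or one occurrence (ZOOPS) on either strand.  The model has
a position probability matrix theta, a 0-order background estimated from
the promoter set, and a per-sequence occurrence prior gamma.

The EM objective reported in ``ll_trace`` is the observed-data
log-likelihood plus the Dirichlet (pseudocount) log-prior on theta; EM
theory guarantees it never decreases, and the tests assert exactly that.
Discovery is MEME-like: candidate start models are built from observed
w-mers (a seeded subsample of up to 200 per width), each is refined by
one EM step, the best is run to convergence, and widths compete by
information content x expected site count.  Found occurrences are masked
with N before the next motif is sought, so successive motifs never share
an occurrence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import IUPAC_NT
from .translated_search import reverse_complement

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PromoterRecord:
    label: str
    sequence: str
    truncated: bool


@dataclass
class PromoterSet:
    records: list[PromoterRecord]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


def extract_promoters(genes, contigs: dict[str, str], window: int = 1000,
                      labels: list[str] | None = None) -> PromoterSet:
    """Upstream windows of gene models on their coding strand.

    ``genes`` yields objects with ``contig``/``contig_id``, ``strand``
    and exon intervals (``exons`` or ``exon_starts``/``exon_ends``).
    A window shorter than requested (gene near the contig edge) is
    flagged truncated; zero upstream gives an empty, flagged entry.
    """
    records = []
    for i, g in enumerate(genes):
        contig_id = getattr(g, "contig_id", None) or getattr(g, "contig")
        seq = contigs[contig_id]
        if hasattr(g, "exons"):
            intervals = sorted(g.exons)
        else:
            intervals = sorted(zip(g.exon_starts, g.exon_ends))
        label = labels[i] if labels else f"{contig_id}"
        if g.strand == "+":
            tss = intervals[0][0]
            lo = max(0, tss - window)
            upstream = seq[lo:tss]
        else:
            tss = intervals[-1][1]
            hi = min(len(seq), tss + window)
            upstream = reverse_complement(seq[tss:hi])
        records.append(PromoterRecord(label, upstream, len(upstream) < window))
    return PromoterSet(records)


@dataclass
class Motif:
    """A discovered ungapped motif (position probability matrix)."""

    width: int
    counts: np.ndarray  # (width, 4) expected site counts + pseudocounts
    pwm: np.ndarray  # (width, 4) probabilities
    consensus: str  # IUPAC, minimal code covering bases with freq >= 0.25
    background: np.ndarray  # (4,)
    gamma: float
    site_count: float  # expected number of occurrences
    ic: float  # total information content, bits
    occurrences: list[tuple[str, int, str, float]] = field(default_factory=list)
    # (promoter label, offset on + strand, strand, posterior)
    ll_trace: list[float] = field(default_factory=list)
    llr: float = 0.0  # log-likelihood gain over the background-only model

    @property
    def ic_per_column(self) -> float:
        return self.ic / self.width

    @property
    def n_parameters(self) -> int:
        return 3 * self.width + 1  # free PWM entries + occurrence prior


def iupac_consensus(pwm: np.ndarray, min_freq: float = 0.25) -> str:
    out = []
    for col in pwm:
        bases = {b for b, f in zip("ACGT", col) if f >= min_freq}
        if not bases:
            bases = {"ACGT"[int(np.argmax(col))]}
        code = min(
            (sym for sym, chars in IUPAC_NT.items() if bases <= set(chars)),
            key=lambda sym: (len(IUPAC_NT[sym]), sym),
        )
        out.append(code)
    return "".join(out)


def _one_hot(seq: str) -> np.ndarray:
    x = np.zeros((len(seq), 4))
    for i, c in enumerate(seq):
        j = _BASE_IDX.get(c)
        if j is not None:
            x[i, j] = 1.0
    return x


def _window_logscores(onehot: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """Log probability ratio (motif/background) of every window.

    Windows containing a non-ACGT position score -inf (excluded).
    """
    w = log_ratio.shape[0]
    L = onehot.shape[0]
    if L < w:
        return np.empty(0)
    view = np.lib.stride_tricks.sliding_window_view(onehot, (w, 4))[:, 0]
    scores = np.einsum("jwb,wb->j", view, log_ratio)
    valid = np.einsum("jwb->j", view) == w
    scores[~valid] = -np.inf
    return scores


class _ZoopsData:
    """Precomputed per-promoter one-hot arrays and window views."""

    def __init__(self, sequences: list[str]):
        self.fwd = [_one_hot(s.upper()) for s in sequences]
        self.rev = [_one_hot(reverse_complement(s.upper())) for s in sequences]
        self.lengths = [len(s) for s in sequences]
        counts = sum(x.sum(axis=0) for x in self.fwd) + 1.0
        self.background = counts / counts.sum()
        self._views: dict[int, list] = {}

    def windows(self, w: int) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
        """Per sequence: flattened (n_win, 4w) window matrices and validity
        masks for both strands (windows touching N are invalid)."""
        if w in self._views:
            return self._views[w]
        out = []
        for fwd, rev in zip(self.fwd, self.rev):
            pair = []
            for onehot in (fwd, rev):
                if onehot.shape[0] < w:
                    pair.append((np.empty((0, 4 * w)), np.empty(0, dtype=bool)))
                    continue
                view = np.lib.stride_tricks.sliding_window_view(onehot, (w, 4))[:, 0]
                flat = view.reshape(view.shape[0], 4 * w)
                pair.append((flat, flat.sum(axis=1) == w))
            out.append((pair[0][0], pair[0][1], pair[1][0], pair[1][1]))
        self._views[w] = out
        return out


def _screen_seeds(data: _ZoopsData, thetas: np.ndarray, gamma: float,
                  pseudocount: float) -> np.ndarray:
    """Objective value of many start models at once (no parameter update).

    ``thetas`` has shape (S, w, 4); returns the (S,) objective vector.
    """
    S, w, _ = thetas.shape
    log_ratio = (np.log(thetas) - np.log(data.background)[None, None, :])
    flat = log_ratio.reshape(S, 4 * w).T  # (4w, S)
    log_none = np.log(max(1.0 - gamma, 1e-300))
    ll = np.full(S, 0.0)
    for win_f, ok_f, win_r, ok_r in data.windows(w):
        scores = np.vstack([win_f, win_r]) @ flat  # (n_win, S)
        ok = np.concatenate([ok_f, ok_r])
        m = int(ok.sum())
        if m == 0:
            ll += log_none
            continue
        scores = scores[ok]
        top = scores.max(axis=0)
        lse = top + np.log(np.exp(scores - top).sum(axis=0))
        ll += np.logaddexp(log_none, np.log(gamma / m) + lse)
    ll += pseudocount * np.log(thetas).reshape(S, -1).sum(axis=1)
    return ll


def _em(data: _ZoopsData, theta: np.ndarray, gamma: float, pseudocount: float,
        max_iter: int, tol: float) -> tuple[np.ndarray, float, list[float], list]:
    """Run ZOOPS EM to convergence; returns (theta, gamma, ll_trace, resp).

    ``resp`` holds per sequence ``(z_fwd, z_rev, z_none)`` from the last
    E-step; the trace is the objective at the start of each iteration and
    is non-decreasing by EM construction.
    """
    w = theta.shape[0]
    log_bg4 = np.tile(np.log(data.background), w)
    ll_trace: list[float] = []
    resp = None
    views = data.windows(w)
    for _ in range(max_iter):
        flat_ratio = np.log(theta).reshape(-1) - log_bg4
        ll = 0.0
        new_counts = np.full(4 * w, pseudocount)
        occ_post = []
        resp = []
        log_none = np.log(max(1.0 - gamma, 1e-300))
        for win_f, ok_f, win_r, ok_r in views:
            n_f = win_f.shape[0]
            scores = np.concatenate([win_f @ flat_ratio, win_r @ flat_ratio])
            ok = np.concatenate([ok_f, ok_r])
            m = int(ok.sum())
            if m == 0:
                occ_post.append(0.0)
                resp.append((np.zeros(n_f), np.zeros(win_r.shape[0]), 1.0))
                ll += log_none
                continue
            scores[~ok] = -np.inf
            top = scores[ok].max()
            lse = top + np.log(np.exp(scores[ok] - top).sum())
            log_total = np.logaddexp(log_none, np.log(gamma / m) + lse)
            ll += log_total
            z = np.exp(np.log(gamma / m) + scores - log_total)
            z_f, z_r = z[:n_f], z[n_f:]
            z_none = np.exp(log_none - log_total)
            occ_post.append(1.0 - z_none)
            resp.append((z_f, z_r, z_none))
            if z_f.size:
                new_counts += z_f @ win_f
            if z_r.size:
                new_counts += z_r @ win_r
        ll += pseudocount * np.log(theta).sum()
        ll_trace.append(float(ll))
        if len(ll_trace) > 1 and abs(ll_trace[-1] - ll_trace[-2]) < tol:
            break
        theta = (new_counts / new_counts.reshape(w, 4).sum(axis=1).repeat(4)).reshape(w, 4)
        gamma = float(np.clip(np.mean(occ_post), 1e-6, 1.0 - 1e-6))
    return theta, gamma, ll_trace, resp


def _information_content(theta: np.ndarray) -> float:
    p = np.clip(theta, 1e-12, 1.0)
    return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


def _seed_theta(wmer: str, strength: float = 0.7) -> np.ndarray:
    w = len(wmer)
    theta = np.full((w, 4), (1.0 - strength) / 3.0)
    for k, c in enumerate(wmer):
        theta[k, _BASE_IDX[c]] = strength
    return theta


def _shift_theta(theta: np.ndarray, shift: int, background: np.ndarray) -> np.ndarray:
    """Slide the motif columns by ``shift``, padding with the background."""
    w = theta.shape[0]
    pad = np.tile(background, (abs(shift), 1))
    if shift > 0:
        return np.vstack([pad, theta[:w - shift]])
    return np.vstack([theta[-shift:], pad])


def discover_motifs(
    promoters: PromoterSet | list[str],
    widths: range | list[int] = range(6, 31),
    n_motifs: int = 10,
    max_seeds: int = 200,
    rng: np.random.Generator | int | None = 0,
    pseudocount: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_ic_per_column: float = 0.5,
    aic_margin: float = 1.5,
) -> list[Motif]:
    """Iterative ZOOPS motif discovery with occurrence masking.

    For each motif: every candidate width is seeded from a subsample of
    observed w-mers, screened by one objective evaluation, the best
    starts are run to convergence (with phase-shift restarts), and the
    width maximizing IC x site count wins.  A candidate is accepted only
    when its log-likelihood gain over the background-only model exceeds
    ``aic_margin`` times its parameter count (EM always overfits random
    sequence by roughly one unit per parameter; real shared motifs gain
    several times that) and its information content stays above
    ``min_ic_per_column`` bits.  Discovery stops after ``n_motifs``
    motifs or at the first unacceptable candidate.
    """
    if isinstance(promoters, PromoterSet):
        labels = [r.label for r in promoters.records]
        working = [r.sequence.upper() for r in promoters.records]
    else:
        labels = [f"p{i}" for i in range(len(promoters))]
        working = [s.upper() for s in promoters]
    if len([s for s in working if s]) < 2:
        raise ValueError("need at least 2 non-empty promoters")
    rng = np.random.default_rng(rng)
    motifs: list[Motif] = []
    for _ in range(n_motifs):
        data = _ZoopsData(working)
        if all((x.sum() == 0) for x in data.fwd):
            break
        best: Motif | None = None
        best_resp = None
        for w in widths:
            wmers = []
            for seq in working:
                for j in range(len(seq) - w + 1):
                    sub = seq[j:j + w]
                    if set(sub) <= set("ACGT"):
                        wmers.append(sub)
            wmers = sorted(set(wmers))
            if not wmers:
                continue
            if len(wmers) > max_seeds:
                idx = rng.choice(len(wmers), size=max_seeds, replace=False)
                wmers = [wmers[i] for i in sorted(idx)]
            gamma0 = 0.5
            thetas = np.stack([_seed_theta(wmer) for wmer in wmers])
            lls = _screen_seeds(data, thetas, gamma0, pseudocount)
            top = np.argsort(lls)[::-1][:3]
            runs = [
                _em(data, thetas[t], gamma0, pseudocount, max_iter, tol)
                for t in top
            ]
            theta, gamma, trace, resp = max(runs, key=lambda r: r[2][-1])
            # phase-shift hill climb: EM frequently locks onto the motif a
            # few columns off; keep sliding while the objective improves
            for _ in range(10):
                improved = False
                for shift in (-3, -2, -1, 1, 2, 3):
                    shifted = _shift_theta(theta, shift, data.background)
                    cand_run = _em(data, shifted, gamma, pseudocount, max_iter, tol)
                    if cand_run[2][-1] > trace[-1] + tol:
                        theta, gamma, trace, resp = cand_run
                        improved = True
                if not improved:
                    break
            site_count = float(sum(1.0 - r[2] for r in resp))
            ic = _information_content(theta)
            llr = trace[-1] - pseudocount * np.log(theta).sum()
            cand = Motif(
                width=w,
                counts=theta * site_count,
                pwm=theta,
                consensus=iupac_consensus(theta),
                background=data.background.copy(),
                gamma=gamma,
                site_count=site_count,
                ic=ic,
                ll_trace=trace,
                llr=float(llr),
            )
            if cand.llr < aic_margin * cand.n_parameters:
                continue  # no better than EM overfit on random sequence
            if cand.ic_per_column < min_ic_per_column:
                continue
            if best is None or cand.ic * cand.site_count > best.ic * best.site_count:
                best = cand
                best_resp = resp
        if best is None:
            break
        # canonical orientation: if most occurrences sit on the minus
        # strand, report the reverse complement instead
        n_minus = sum(
            1.0 - z_none > 0.5 and (z_r.size and z_r.max() > (z_f.max() if z_f.size else -1))
            for z_f, z_r, z_none in best_resp
        )
        n_present = sum(1.0 - z_none > 0.5 for _, _, z_none in best_resp)
        if n_present and n_minus > n_present / 2:
            best.pwm = best.pwm[::-1, ::-1].copy()
            best.counts = best.counts[::-1, ::-1].copy()
            best.consensus = iupac_consensus(best.pwm)
            # a minus-strand window at revcomp offset j covers the plus
            # interval starting at (n_windows - 1 - j), so swap + reverse
            best_resp = [(z_r[::-1], z_f[::-1], z_none) for z_f, z_r, z_none in best_resp]
        # record and mask ZOOPS occurrences (posterior presence > 0.5)
        for i, (seq, (z_f, z_r, z_none)) in enumerate(zip(working, best_resp)):
            if 1.0 - z_none <= 0.5 or z_f.size + z_r.size == 0:
                continue
            scores = np.concatenate([z_f, z_r])
            j = int(np.argmax(scores))
            if j < z_f.size:
                strand, start = "+", j
            else:
                strand, start = "-", len(seq) - (j - z_f.size) - best.width
            best.occurrences.append((labels[i], start, strand, float(scores[j])))
            working[i] = seq[:start] + "N" * best.width + seq[start + best.width:]
        motifs.append(best)
    return motifs


def consensus_score(motif: Motif) -> float:
    """Log-odds score of the best-matching sequence (the PWM argmax)."""
    log_ratio = np.log(motif.pwm) - np.log(motif.background)[None, :]
    return float(log_ratio.max(axis=1).sum())


def scan_motif(motif: Motif, sequence: str,
               threshold: float | None = None) -> list[tuple[int, str, float]]:
    """Scan both strands with the motif log-odds; report matches above
    the threshold (default: 80% of the consensus score)."""
    sequence = sequence.upper()
    if motif.width > len(sequence):
        return []
    if threshold is None:
        threshold = 0.8 * consensus_score(motif)
    log_ratio = np.log(motif.pwm) - np.log(motif.background)[None, :]
    matches = []
    s_f = _window_logscores(_one_hot(sequence), log_ratio)
    s_r = _window_logscores(_one_hot(reverse_complement(sequence)), log_ratio)
    for j, sc in enumerate(s_f):
        if sc >= threshold:
            matches.append((j, "+", float(sc)))
    for j, sc in enumerate(s_r):
        if sc >= threshold:
            matches.append((len(sequence) - j - motif.width, "-", float(sc)))
    matches.sort(key=lambda m: (m[0], m[1]))
    return matches
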
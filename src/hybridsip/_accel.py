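"""Read-assignment kernels: hash-table k-mer lookup, numba-accelerated.

The reference index is an open-addressing hash table (power-of-two size,
linear probing, splitmix64-style finalizer) mapping canonical k-mers to a
packed (contig, position) word. Assignment walks each read's k-mers,
counts shared k-mers per contig, picks the contig with the highest count
(ties to the lowest contig index, i.e. lexicographically smallest id once
contigs are sorted), and records the diagonal of the first matching k-mer
on the winning contig. A pure-numpy fallback implements the identical
semantics when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

EMPTY = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _mix(x):
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


@njit(cache=True)
def build_table(keys, vals, table_keys, table_vals):
    mask = np.uint64(len(table_keys) - 1)
    for i in range(len(keys)):
        key = keys[i]
        slot = _mix(key) & mask
        while True:
            cur = table_keys[slot]
            if cur == EMPTY:
                table_keys[slot] = key
                table_vals[slot] = vals[i]
                break
            if cur == key:  # first insertion wins (duplicates are collisions)
                break
            slot = (slot + np.uint64(1)) & mask


@njit(cache=True)
def assign_reads(codes, k, table_keys, table_vals, nc, contig_lengths):
    """Assign each read (row of base codes) to a contig.

    Packs canonical k-mers on the fly (rolling 2-bit encoding), looks each
    up in the hash table, counts shared k-mers per contig, and picks the
    winner (ties to the lowest contig index). Returns (best_contig,
    n_shared, aligned_start, aligned_end) per read; best_contig is -1 for
    unmapped reads. aligned_* is the read's placement interval on the
    winning contig — the diagonal of the first matching k-mer — clipped to
    the contig.
    """
    n, read_length = codes.shape
    m = read_length - k + 1
    kmask = np.uint64((1 << (2 * k)) - 1)
    rcshift = np.uint64(2 * k - 2)
    two = np.uint64(2)
    three = np.uint64(3)
    mask = np.uint64(len(table_keys) - 1)
    best_contig = np.full(n, -1, dtype=np.int64)
    starts = np.zeros(n, dtype=np.int64)
    ends = np.zeros(n, dtype=np.int64)
    shared = np.zeros(n, dtype=np.int64)
    counts = np.zeros(nc, dtype=np.int64)
    first_off = np.zeros(nc, dtype=np.int64)
    first_pos = np.zeros(nc, dtype=np.int64)
    touched = np.empty(m, dtype=np.int64)
    for r in range(n):
        ntouched = 0
        fwd = np.uint64(0)
        rc = np.uint64(0)
        for j in range(k - 1):
            b = np.uint64(codes[r, j])
            fwd = ((fwd << two) | b) & kmask
            rc = (rc >> two) | ((three - b) << rcshift)
        for off in range(m):
            b = np.uint64(codes[r, off + k - 1])
            fwd = ((fwd << two) | b) & kmask
            rc = (rc >> two) | ((three - b) << rcshift)
            key = fwd if fwd < rc else rc
            slot = _mix(key) & mask
            while True:
                cur = table_keys[slot]
                if cur == EMPTY:
                    break
                if cur == key:
                    val = table_vals[slot]
                    cid = val >> 32
                    pos = val & 0xFFFFFFFF
                    if counts[cid] == 0:
                        touched[ntouched] = cid
                        ntouched += 1
                        first_off[cid] = off
                        first_pos[cid] = pos
                    counts[cid] += 1
                    break
                slot = (slot + np.uint64(1)) & mask
        if ntouched > 0:
            best = -1
            best_count = 0
            for t in range(ntouched):
                cid = touched[t]
                if counts[cid] > best_count or (
                    counts[cid] == best_count and cid < best
                ):
                    best = cid
                    best_count = counts[cid]
            best_contig[r] = best
            shared[r] = best_count
            diag = first_pos[best] - first_off[best]
            lo = diag if diag > 0 else 0
            hi = diag + read_length
            if hi > contig_lengths[best]:
                hi = contig_lengths[best]
            starts[r] = lo
            ends[r] = hi
            for t in range(ntouched):
                counts[touched[t]] = 0
    return best_contig, shared, starts, ends


def assign_reads_numpy(codes, k, index_kmers, index_contig, index_pos, nc, contig_lengths):
    """Vectorised fallback with the same assignment semantics."""
    from . import _codec

    n, read_length = codes.shape
    kmers = _codec.canonical_kmers(codes, k)
    m = kmers.shape[1]
    flat = kmers.ravel()
    order = np.argsort(flat, kind="stable")
    svals = flat[order]
    if len(index_kmers):
        sidx = np.searchsorted(index_kmers, svals)
        sidx = np.minimum(sidx, len(index_kmers) - 1)
        hit_s = index_kmers[sidx] == svals
    else:
        sidx = np.zeros(len(svals), dtype=np.int64)
        hit_s = np.zeros(len(svals), dtype=bool)
    orig = order[hit_s]  # positions in (read, offset) raveled order
    resort = np.argsort(orig, kind="stable")
    orig = orig[resort]
    matched_idx = sidx[hit_s][resort]
    read_idx = orig // m
    offsets = orig % m
    cids = index_contig[matched_idx].astype(np.int64)
    cpos = index_pos[matched_idx].astype(np.int64)

    count_matrix = np.bincount(read_idx * nc + cids, minlength=n * nc).reshape(n, nc)
    best = np.argmax(count_matrix, axis=1)
    best_count = np.take_along_axis(count_matrix, best[:, None], axis=1).ravel()
    mapped = best_count > 0

    win = cids == best[read_idx]
    r_w, off_w, pos_w = read_idx[win], offsets[win], cpos[win]
    if len(r_w):
        firsts = np.concatenate(([0], np.flatnonzero(r_w[1:] != r_w[:-1]) + 1))
        r_f = r_w[firsts]
        diag = pos_w[firsts] - off_w[firsts]
    else:
        r_f = np.empty(0, dtype=np.int64)
        diag = np.empty(0, dtype=np.int64)

    best_contig = np.where(mapped, best, -1).astype(np.int64)
    starts = np.zeros(n, dtype=np.int64)
    ends = np.zeros(n, dtype=np.int64)
    c_f = best[r_f]
    starts[r_f] = np.clip(diag, 0, contig_lengths[c_f])
    ends[r_f] = np.clip(diag + read_length, 0, contig_lengths[c_f])
    return best_contig, best_count.astype(np.int64), starts, ends


def make_table(keys: np.ndarray, contig: np.ndarray, pos: np.ndarray):
    """Build the open-addressing table from unique canonical k-mers."""
    size = 1
    while size < max(2 * len(keys), 16):
        size *= 2
    table_keys = np.full(size, EMPTY, dtype=np.uint64)
    table_vals = np.zeros(size, dtype=np.int64)
    vals = (contig.astype(np.int64) << 32) | pos.astype(np.int64)
    if len(keys):
        build_table(keys, vals, table_keys, table_vals)
    return table_keys, table_vals
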
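"""Compiled (numba) kernels for read scanning and cascade counting.

These implement exactly the same hashing and filter semantics as the scalar
APIs in :mod:`kmerstat.hashing` and :mod:`kmerstat.bloom` — the test suite
asserts bit-for-bit agreement — but run the per-occurrence inner loops at
native speed.  Everything here is an implementation detail; the public
surface is :mod:`kmerstat.cascade`.

Conventions shared with the scalar code:

* base hash = min(forward, reverse) xor-rotate hash over per-base constants;
* derived hash ``i`` = splitmix64(base + i * ODD);
* filter index = derived hash mod m;
* packed canonical k-mer (k <= 32) = min(2-bit big-endian pack of the
  forward strand, same pack of the reverse complement); numeric order of
  these packs equals lexicographic order of the k-mer strings.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

_TBL = np.array(
    [0x3C8BFBB395C60474, 0x3193C18562A02B4C, 0x20323ED082572324, 0x295549F54BE24456],
    dtype=np.uint64,
)
_ODD = np.uint64(0xD6E8FEB86659FD93)
_MIX1 = np.uint64(0x9E3779B97F4A7C15)
_MIX2 = np.uint64(0xBF58476D1CE4E5B9)
_MIX3 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _rol(x, s):
    s = s & np.uint64(63)
    if s == np.uint64(0):
        return x
    return (x << s) | (x >> (np.uint64(64) - s))


@njit(cache=True, inline="always")
def _mix(x):
    x = x + _MIX1
    z = x
    z = (z ^ (z >> np.uint64(30))) * _MIX2
    z = (z ^ (z >> np.uint64(27))) * _MIX3
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _derive(base, i):
    return _mix(base + np.uint64(i) * _ODD)


@njit(cache=True)
def scan_kernel(codes, offsets, k, do_pack, out_hash, out_read, out_packed):
    """Hash every valid window of every read in a flat code array.

    ``codes`` holds 2-bit base codes (4 = invalid) for all reads laid out
    back-to-back; ``offsets`` (len = n_reads + 1) delimits reads.  Windows
    containing an invalid base are skipped.  Returns the number of windows
    emitted into the out arrays.
    """
    nw = 0
    uk = np.uint64(k)
    two_k_mask = np.uint64(0) - np.uint64(1) if k >= 32 else (np.uint64(1) << (np.uint64(2) * uk)) - np.uint64(1)
    for ri in range(len(offsets) - 1):
        s = offsets[ri]
        e = offsets[ri + 1]
        if e - s < k:
            continue
        valid_run = 0
        f = np.uint64(0)
        r = np.uint64(0)
        pk = np.uint64(0)
        rk = np.uint64(0)
        for pos in range(s, e):
            c = np.uint64(codes[pos])
            if c > np.uint64(3):
                valid_run = 0
                continue
            valid_run += 1
            if valid_run < k:
                continue
            if valid_run == k:
                f = np.uint64(0)
                r = np.uint64(0)
                pk = np.uint64(0)
                rk = np.uint64(0)
                for j in range(k):
                    cc = np.uint64(codes[pos - k + 1 + j])
                    f ^= _rol(_TBL[cc], np.uint64(k - 1 - j))
                    r ^= _rol(_TBL[np.uint64(3) - cc], np.uint64(j))
                    if do_pack:
                        pk = (pk << np.uint64(2)) | cc
                        rk |= (np.uint64(3) - cc) << (np.uint64(2) * np.uint64(j))
            else:
                oc = np.uint64(codes[pos - k])
                ic = c
                f = _rol(f, np.uint64(1)) ^ _rol(_TBL[oc], uk) ^ _TBL[ic]
                r = (
                    _rol(r, np.uint64(63))
                    ^ _rol(_TBL[np.uint64(3) - oc], np.uint64(63))
                    ^ _rol(_TBL[np.uint64(3) - ic], uk - np.uint64(1))
                )
                if do_pack:
                    pk = ((pk << np.uint64(2)) | ic) & two_k_mask
                    rk = (rk >> np.uint64(2)) | (
                        (np.uint64(3) - ic) << (np.uint64(2) * (uk - np.uint64(1)))
                    )
            out_hash[nw] = f if f < r else r
            out_read[nw] = ri
            if do_pack:
                out_packed[nw] = pk if pk < rk else rk
            nw += 1
    return nw


@njit(cache=True)
def scan_kernel_spaced(codes, offsets, k, care, out_hash, out_read):
    """Spaced-seed variant: hash the care-position substring of each window."""
    nw = 0
    w = len(care)
    for ri in range(len(offsets) - 1):
        s = offsets[ri]
        e = offsets[ri + 1]
        if e - s < k:
            continue
        valid_run = 0
        for pos in range(s, e):
            if codes[pos] > 3:
                valid_run = 0
                continue
            valid_run += 1
            if valid_run < k:
                continue
            start = pos - k + 1
            f = np.uint64(0)
            r = np.uint64(0)
            for j in range(w):
                cc = np.uint64(codes[start + care[j]])
                f ^= _rol(_TBL[cc], np.uint64(w - 1 - j))
                r ^= _rol(_TBL[np.uint64(3) - cc], np.uint64(j))
            out_hash[nw] = f if f < r else r
            out_read[nw] = ri
            nw += 1
    return nw


@njit(cache=True)
def hashes_from_packed(packed, k, out_hash):
    """Base hashes for canonical-packed k-mers (inverse of the pack step)."""
    for i in range(len(packed)):
        p = packed[i]
        f = np.uint64(0)
        r = np.uint64(0)
        for j in range(k):
            cc = (p >> (np.uint64(2) * np.uint64(k - 1 - j))) & np.uint64(3)
            f ^= _rol(_TBL[cc], np.uint64(k - 1 - j))
            r ^= _rol(_TBL[np.uint64(3) - cc], np.uint64(j))
        out_hash[i] = f if f < r else r


@njit(cache=True, inline="always")
def _bf_contains(bits, m, base, h):
    for i in range(h):
        idx = _derive(base, i) % m
        if (bits[idx >> np.uint64(3)] >> (idx & np.uint64(7))) & np.uint8(1) == 0:
            return False
    return True


@njit(cache=True, inline="always")
def _bf_insert(bits, m, base, h):
    for i in range(h):
        idx = _derive(base, i) % m
        bits[idx >> np.uint64(3)] |= np.uint8(1) << np.uint8(idx & np.uint64(7))


@njit(cache=True, inline="always")
def _cbf_min(cnt, m, base, h):
    mn = np.uint64(0) - np.uint64(1)
    for i in range(h):
        idx = _derive(base, i) % m
        v = np.uint64(cnt[idx])
        if v < mn:
            mn = v
    return mn


@njit(cache=True, inline="always")
def _cbf_inc(cnt, m, base, h, cap):
    """Minimal-increase increment; returns the new reported (min) count."""
    mn = _cbf_min(cnt, m, base, h)
    if mn >= cap:
        return mn
    for i in range(h):
        idx = _derive(base, i) % m
        if np.uint64(cnt[idx]) == mn:
            cnt[idx] = mn + np.uint64(1)
    return mn + np.uint64(1)


@njit(cache=True, inline="always")
def _cbf_dec(cnt, m, base, h, amount):
    for i in range(h):
        idx = _derive(base, i) % m
        v = np.uint64(cnt[idx])
        if v != np.uint64(0):  # counters untouched this pass keep their value;
            dec = amount if amount < v else v
            cnt[idx] = v - dec


@njit(cache=True)
def count_kernel(
    hashes,
    read_ids,
    h,
    cmin,
    cmax,
    use_global,
    gbits,
    gm,
    use_inter,
    icnt,
    im,
    out_is_bf,
    obits,
    ocnt,
    om,
    ocap,
    use_sec,
    sbits,
    sm,
    use_depth,
    dcnt,
    dm,
    dcap,
    scratch_bits,
    scratch_m,
    scratch_pos,
):
    """Apply the cascade (and optional depth extraction) to a window stream.

    ``hashes``/``read_ids`` come from a scan kernel; reads must be contiguous
    so the per-read scratch BF can be cleared at read boundaries.  Semantics
    per occurrence (matching CountStore's documented contract):

    * occurrence 1 sets the global BF (when allocated, i.e. cmin >= 2);
    * occurrences 2..cmin-1 increment the intermediate CBF (cmin >= 3);
    * occurrence cmin and later go to the output structure; reported count =
      stored counter + (cmin - 1);
    * a reported count crossing cmax inserts the k-mer into the secondary BF
      (if requested) and decrements its own reported value from its counters.
    """
    uh = h
    ugm = np.uint64(gm)
    uim = np.uint64(im)
    uom = np.uint64(om)
    usm = np.uint64(sm)
    udm = np.uint64(dm)
    uscm = np.uint64(scratch_m)
    ucap = np.uint64(ocap)
    udcap = np.uint64(dcap)
    ucmin = np.uint64(cmin)
    ucmax = np.uint64(cmax)
    inter_cap = ucmin - np.uint64(2) if cmin >= 2 else np.uint64(0)
    cur_read = np.int64(-1)
    n_scratch = 0
    for wi in range(len(hashes)):
        base = hashes[wi]
        if use_depth:
            rid = read_ids[wi]
            if rid != cur_read:
                for i in range(n_scratch):
                    scratch_bits[scratch_pos[i] >> np.uint64(3)] = np.uint8(0)
                n_scratch = 0
                cur_read = rid
            new_in_read = False
            for i in range(uh):
                idx = _derive(base, i) % uscm
                if (scratch_bits[idx >> np.uint64(3)] >> (idx & np.uint64(7))) & np.uint8(1) == 0:
                    new_in_read = True
                    break
            if new_in_read:
                for i in range(uh):
                    idx = _derive(base, i) % uscm
                    scratch_bits[idx >> np.uint64(3)] |= np.uint8(1) << np.uint8(idx & np.uint64(7))
                    scratch_pos[n_scratch] = idx
                    n_scratch += 1
                _cbf_inc(dcnt, udm, base, uh, udcap)
        if use_sec and _bf_contains(sbits, usm, base, uh):
            continue
        if cmin > 1:
            if not _bf_contains(gbits, ugm, base, uh):
                _bf_insert(gbits, ugm, base, uh)
                continue
            if use_inter:
                icount = _cbf_min(icnt, uim, base, uh)
                if icount < inter_cap:
                    _cbf_inc(icnt, uim, base, uh, inter_cap)
                    continue
        if out_is_bf:
            _bf_insert(obits, uom, base, uh)
            continue
        stored = _cbf_inc(ocnt, uom, base, uh, ucap)
        reported = stored + ucmin - np.uint64(1)
        if reported > ucmax:
            if use_sec:
                _bf_insert(sbits, usm, base, uh)
            _cbf_dec(ocnt, uom, base, uh, reported)
    # clear scratch set by the final read so the buffer can be reused
    if use_depth:
        for i in range(n_scratch):
            scratch_bits[scratch_pos[i] >> np.uint64(3)] = np.uint8(0)
    return 0


@njit(cache=True)
def query_counts_kernel(hashes, h, cmin, ocnt, om, ocap, use_sec, sbits, sm, out):
    """Reported counts for an array of base hashes (counts output)."""
    uom = np.uint64(om)
    usm = np.uint64(sm)
    for i in range(len(hashes)):
        base = hashes[i]
        if use_sec and _bf_contains(sbits, usm, base, h):
            out[i] = 0
            continue
        stored = _cbf_min(ocnt, uom, base, h)
        if stored == np.uint64(0):
            out[i] = 0
        else:
            out[i] = stored + np.uint64(cmin) - np.uint64(1)


@njit(cache=True)
def query_membership_kernel(hashes, h, obits, om, out):
    uom = np.uint64(om)
    for i in range(len(hashes)):
        out[i] = 1 if _bf_contains(obits, uom, hashes[i], h) else 0


@njit(cache=True)
def query_cbf_kernel(hashes, h, cnt, m, out):
    um = np.uint64(m)
    for i in range(len(hashes)):
        out[i] = _cbf_min(cnt, um, hashes[i], h)
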
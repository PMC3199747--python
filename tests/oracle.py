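"""Independent brute-force reference implementations used only by tests.

These apply the decision rules residue by residue with plain Python loops,
deliberately sharing no code with the package's vectorized implementation.
"""

from dichot.model import SegmentLabel


def brute_force_labels(protein, bundle, config):
    """Label each residue by direct application of the precedence rules,
    then re-scan for sub-threshold candidate-CD runs."""
    n = protein.length
    labels = []
    for i in range(n):
        covered_kd = False
        covered_short = False
        for h in bundle.hits:
            if h.interval.start <= i < h.interval.end:
                if h.subject_length >= config.short_subject_threshold:
                    covered_kd = True
                else:
                    covered_short = True
        for r in bundle.regions:
            if r.interval.start <= i < r.interval.end:
                covered_kd = True
        for p in bundle.pfam:
            if p.pfam_id in config.fibrous_pfam_ids and p.interval.start <= i < p.interval.end:
                covered_kd = True
        if covered_kd:
            labels.append("KD")
            continue
        a = str(bundle.track_a.calls[i])
        b = str(bundle.track_b.calls[i])
        if a == "ID" or b == "ID":
            labels.append("ID")
        else:  # b == "SD", a not ID
            labels.append("CD")

    # second pass: demote candidate-CD runs that are too short
    out = list(labels)
    i = 0
    while i < n:
        if labels[i] == "CD":
            j = i
            while j < n and labels[j] == "CD":
                j += 1
            run = j - i
            short = run <= config.cd_min_length if config.cd_strictly_longer else run < config.cd_min_length
            if short:
                for k in range(i, j):
                    out[k] = "ID"
            i = j
        else:
            i += 1
    return out


def longest_id_run(label_list):
    """Length of the longest contiguous ID run in a label sequence."""
    best = cur = 0
    for lab in label_list:
        if lab == "ID":
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def run_length_encode(label_list):
    out = []
    for lab in label_list:
        if out and out[-1][1] == lab:
            out[-1][0] += 1
        else:
            out.append([1, lab])
    return [(n, lab) for n, lab in out]


def label_counts(segmentations):
    counts = {lab: 0 for lab in SegmentLabel}
    for seg in segmentations:
        for s in seg.segments:
            counts[s.label] += len(s.interval)
    return counts
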
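"""Independent truth-table oracle for the strict inheritance predicates.

Written as a literal, rule-by-rule transcription of the documented
segregation semantics, structured differently from the library code so
the two can be compared over exhaustive enumerations.  Members are
(sid, father_or_None, mother_or_None) tuples; ``status`` maps sid to
'a'/'u'/'?'; ``gt`` maps sid to 0/1/2/None.
"""


def _full_trio(members, status):
    return any(
        fa is not None and mo is not None and status[sid] == "a"
        for sid, fa, mo in members
    )


def _parents_of(members, sid):
    for s, fa, mo in members:
        if s == sid:
            return [p for p in (fa, mo) if p is not None]
    raise KeyError(sid)


def oracle(mode, members, status, gt):
    affected = [sid for sid, _, _ in members if status[sid] == "a"]
    unaffected = [sid for sid, _, _ in members if status[sid] == "u"]
    if not affected:
        return False
    if not _full_trio(members, status):
        return False

    if mode == "dominant":
        if any(gt[a] != 1 for a in affected):
            return False
        if any(gt[u] is None or gt[u] > 0 for u in unaffected):
            return False
        for a in affected:
            for p in _parents_of(members, a):
                if status[p] == "a" and gt[p] is not None and gt[p] >= 1:
                    return True
        return False

    if mode == "recessive":
        if any(gt[a] != 2 for a in affected):
            return False
        for a in affected:
            for p in _parents_of(members, a):
                if gt[p] != 1:
                    return False
        if any(gt[u] is None or gt[u] == 2 for u in unaffected):
            return False
        return True

    if mode == "de_novo":
        if any(gt[a] != 1 for a in affected):
            return False
        for a in affected:
            for p in _parents_of(members, a):
                if gt[p] != 0:
                    return False
        if any(gt[u] != 0 for u in unaffected):
            return False
        return any(
            fa is not None and mo is not None and status[sid] == "a"
            for sid, fa, mo in members
        )

    raise ValueError(mode)
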
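"""Independent brute-force oracles used to cross-check the library.

Everything here works directly on a knowledge base's raw data (term dict,
edge set, profile dict, record list) with plain graph walks and nested
loops; none of it calls the library's reasoning, query, or statistics code.
"""

from collections import defaultdict


def _parent_map(kb):
    parents = defaultdict(set)
    for edge in kb.edges:
        parents[edge.child].add(edge.parent)
    return parents


def _child_map(kb):
    children = defaultdict(set)
    for edge in kb.edges:
        children[edge.parent].add(edge.child)
    return children


def _reach(adjacency, start):
    seen, stack = set(), [start]
    while stack:
        for nxt in adjacency[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def ancestors_bfs(kb, term_id):
    """Transitive parents by reachability over reversed is_a edges."""
    return _reach(_parent_map(kb), term_id)


def descendants_bfs(kb, term_id):
    return _reach(_child_map(kb), term_id)


def has_cycle(edges):
    """DFS three-color cycle detection over (child, parent) pairs."""
    adjacency = defaultdict(set)
    nodes = set()
    for child, parent in edges:
        adjacency[child].add(parent)
        nodes.update((child, parent))
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}

    def visit(n):
        color[n] = GRAY
        for m in adjacency[n]:
            if color[m] == GRAY or (color[m] == WHITE and visit(m)):
                return True
        color[n] = BLACK
        return False

    return any(color[n] == WHITE and visit(n) for n in nodes)


def drugs_in_class(kb, class_id):
    """Scan every drug, testing membership against {class} ∪ descendants."""
    under = {class_id} | descendants_bfs(kb, class_id)
    members = set()
    for term in kb.terms.values():
        if term.kind.value != "drug":
            continue
        prof = kb.profiles.get(term.id)
        moas = prof.moas if prof else set()
        if any(m in under for m in moas) or term.id in under:
            members.add(term.id)
    return members


def _record_ok(kb, record, age, disease):
    if age is not None and record.age != age:
        return False
    if disease is not None:
        allowed = {disease} | descendants_bfs(kb, disease)
        if record.disease is None or record.disease not in allowed:
            return False
    return True


def query_quadruples(kb, moa_class=None, age=None, disease=None, drug=None):
    """Nested-loop join of records and profiles under all filters; returns
    a set of (drug, moa, disease, ae, age-token) tuples."""
    members = drugs_in_class(kb, moa_class) if moa_class is not None else None
    moa_under = (
        {moa_class} | descendants_bfs(kb, moa_class) if moa_class is not None else None
    )
    out = set()
    for record in kb.records:
        if drug is not None and record.drug != drug:
            continue
        if members is not None and record.drug not in members:
            continue
        if not _record_ok(kb, record, age, disease):
            continue
        prof = kb.profiles.get(record.drug)
        moas = set(prof.moas) if prof else set()
        if moa_under is not None:
            moas = {m for m in moas if m in moa_under} or {None}
        elif not moas:
            moas = {None}
        for moa in moas:
            out.add((record.drug, moa, record.disease, record.ae, record.age.value))
    return out


def ae_counts(kb, age=None):
    """Scenario counting: distinct (drug, age, disease) contexts per AE."""
    seen = defaultdict(set)
    for record in kb.records:
        if age is not None and record.age != age:
            continue
        seen[record.ae].add((record.drug, record.age.value, record.disease))
    return {ae: len(s) for ae, s in seen.items()}


def pcr_ratio(kb, class_id, ae_id, age=None, disease=None):
    """(n_assoc, n_total) by explicit membership/association counting."""
    members = drugs_in_class(kb, class_id)
    associated = set()
    for record in kb.records:
        if record.ae == ae_id and record.drug in members:
            if _record_ok(kb, record, age, disease):
                associated.add(record.drug)
    return len(associated), len(members)
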
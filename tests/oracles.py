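"""Independent brute-force reference implementations used as test oracles.

These re-derive every rule directly from its written definition by exhaustive
enumeration over (claim, code, day) triples and never call the package's
algorithms; the catalog object is used only as a table of entries.
"""

import bisect

NEWBORN_MAX = 28
PEDIATRIC_MAX = 18 * 365
RANK = {"definite": 0, "probable": 1, "possible": 2,
        "genetic_test": 3, "other_cpt_hcpcs": 4}


def _norm(code):
    return str(code).strip().upper().replace(".", "")


def _diagnosis_entry(catalog, code, day):
    code = _norm(code)
    for system in ("ICD10", "ICD9"):
        for e in catalog.diagnosis_entries:
            if _norm(e.code) == code and e.code_system == system:
                if e.age_min_days <= day and (e.age_max_days is None
                                              or day <= e.age_max_days):
                    return e
    return None


def _procedure_category(catalog, code):
    code = _norm(code)
    for system in ("CPT", "HCPCS"):
        for e in catalog.procedure_entries:
            if _norm(e.code) == code and e.code_system == system:
                return e.category
    return None


def _revenue_unit(catalog, code):
    code = _norm(code)
    for e in catalog.revenue_entries:
        if _norm(e.code) == code:
            return e.unit
    return None


def _patient_claims(dataset, pid):
    frame = dataset.claims
    return frame[frame["patient_id"] == pid]


def _spans(dataset, pid):
    frame = dataset.enrollment
    rows = frame[frame["patient_id"] == pid]
    return sorted((int(s), int(e))
                  for s, e in zip(rows["start_day"], rows["end_day"]))


def oracle_index(dataset, catalog, pid, cohort):
    """(day, category, code) of the first qualifying event, or None."""
    candidates = []
    for _, row in _patient_claims(dataset, pid).iterrows():
        day = int(row["service_day"])
        for code in row["diagnosis_codes"]:
            e = _diagnosis_entry(catalog, code, day)
            if e is None or e.easy_to_diagnose:
                continue
            if cohort == "mca_id_dd_e" and not (
                    e.mca_specific_flag or e.anomaly_flag or e.id_flag
                    or e.dd_flag or e.e_flag):
                continue
            candidates.append((day, RANK[e.tier], _norm(code), e.tier))
        if cohort == "broad":
            for code in row["procedure_codes"]:
                cat = _procedure_category(catalog, code)
                if cat is None:
                    continue
                label = "genetic_test" if cat == "genetic_test" else "other_cpt_hcpcs"
                candidates.append((day, RANK[label], _norm(code), label))
    if not candidates:
        return None
    day, _, code, category = min(candidates)
    return day, category, code


def oracle_enrolled(dataset, pid, day):
    lookback = min(180, day)
    return any(s <= day - lookback and e >= day for s, e in _spans(dataset, pid))


def oracle_has_mca(dataset, catalog, pid):
    systems = set()
    for _, row in _patient_claims(dataset, pid).iterrows():
        day = int(row["service_day"])
        for code in row["diagnosis_codes"]:
            e = _diagnosis_entry(catalog, code, day)
            if e is None or e.easy_to_diagnose:
                continue
            if e.mca_specific_flag:
                return True
            if e.anomaly_flag:
                systems.add(e.organ_system)
    return len(systems) >= 2


def _has_idde(dataset, catalog, pid):
    for _, row in _patient_claims(dataset, pid).iterrows():
        day = int(row["service_day"])
        for code in row["diagnosis_codes"]:
            e = _diagnosis_entry(catalog, code, day)
            if e is not None and not e.easy_to_diagnose and (
                    e.id_flag or e.dd_flag or e.e_flag):
                return True
    return False


def _has_genetic_test(dataset, catalog, pid):
    for _, row in _patient_claims(dataset, pid).iterrows():
        for code in row["procedure_codes"]:
            if _procedure_category(catalog, code) == "genetic_test":
                return True
    return False


def _has_nicu(dataset, catalog, pid):
    spans = _spans(dataset, pid)
    for _, row in _patient_claims(dataset, pid).iterrows():
        day = int(row["service_day"])
        if any(_revenue_unit(catalog, c) == "NICU" for c in row["revenue_codes"]):
            if any(s <= day <= e for s, e in spans):
                return True
    return False


def oracle_assign(dataset, catalog):
    """pid -> dict(in_broad, in_mca_id_dd_e, in_conservative, population)."""
    out = {}
    for pid in dataset.patients["patient_id"].astype(str):
        broad = oracle_index(dataset, catalog, pid, "broad")
        mca = oracle_index(dataset, catalog, pid, "mca_id_dd_e")
        cons = oracle_index(dataset, catalog, pid, "conservative")

        def eligible(event):
            return (event is not None and oracle_enrolled(dataset, pid, event[0])
                    and event[0] <= PEDIATRIC_MAX)

        in_broad = eligible(broad)
        in_mca = (eligible(mca) and in_broad
                  and (oracle_has_mca(dataset, catalog, pid)
                       or _has_idde(dataset, catalog, pid)))
        in_cons = (eligible(cons) and in_broad
                   and cons[1] in ("possible", "probable")
                   and _has_genetic_test(dataset, catalog, pid))
        if broad is None:
            population = "control" if _spans(dataset, pid) else "excluded"
        elif not in_broad:
            population = "excluded"
        elif broad[0] <= NEWBORN_MAX and _has_nicu(dataset, catalog, pid):
            population = "critically_ill_newborn"
        else:
            population = "pediatric"
        out[pid] = {"in_broad": in_broad, "in_mca_id_dd_e": in_mca,
                    "in_conservative": in_cons, "population": population}
    return out


# -- outcome oracles -------------------------------------------------------

def oracle_genetic_tests(dataset, catalog, pid, index_day):
    """(n distinct day x code tests on/after index, day of first test or None)."""
    tests = set()
    for _, row in _patient_claims(dataset, pid).iterrows():
        day = int(row["service_day"])
        if day < index_day:
            continue
        for code in row["procedure_codes"]:
            if _procedure_category(catalog, code) == "genetic_test":
                tests.add((day, _norm(code)))
    if not tests:
        return 0, None
    return len(tests), min(d for d, _ in tests)


def oracle_nicu_total_days(dataset, catalog, pid, gap=1):
    spans = _spans(dataset, pid)
    days = sorted({int(row["service_day"])
                   for _, row in _patient_claims(dataset, pid).iterrows()
                   if any(_revenue_unit(catalog, c) == "NICU"
                          for c in row["revenue_codes"])
                   and any(s <= int(row["service_day"]) <= e for s, e in spans)})
    return len(days)  # total across runs regardless of splitting


def oracle_transitions(dataset, catalog, pid, index_day, index_category):
    reached = set()
    for _, row in _patient_claims(dataset, pid).iterrows():
        day = int(row["service_day"])
        if day <= index_day or not row["diagnosis_codes"]:
            continue
        e = _diagnosis_entry(catalog, row["diagnosis_codes"][0], day)
        if e is not None:
            reached.add(e.tier)
    rows = set()
    for src, dst in (("possible", "probable"), ("possible", "definite"),
                     ("probable", "definite"), ("genetic_test", "definite"),
                     ("other_cpt_hcpcs", "definite")):
        if index_category == src and dst in reached:
            if src in ("possible", "probable") and RANK[dst] >= RANK[src]:
                continue
            rows.add((src, dst))
    return rows


def oracle_cost_bins(dataset, pid, index_day, n_bins):
    """[(contributes, total, inpatient, outpatient)] per bin for one patient."""
    spans = _spans(dataset, pid)
    out = []
    for k in range(n_bins):
        lo, hi = index_day + 30 * k, index_day + 30 * (k + 1) - 1
        contributes = any(s <= lo and hi <= e for s, e in spans)
        total = inpt = outpt = 0.0
        if contributes:
            for _, row in _patient_claims(dataset, pid).iterrows():
                if lo <= int(row["service_day"]) <= hi:
                    total += row["allowed_amount"]
                    if row["setting"] == "inpatient":
                        inpt += row["allowed_amount"]
                    elif row["setting"] == "outpatient":
                        outpt += row["allowed_amount"]
        out.append((contributes, total, inpt, outpt))
    return out


# -- matching oracles ------------------------------------------------------

def oracle_signature(row, rules):
    signature = []
    for covariate, edges in rules.items():
        value = row[covariate]
        if edges is None:
            signature.append(value)
        else:
            edges = list(edges)
            idx = bisect.bisect_right(edges, float(value)) - 1
            signature.append(min(max(idx, 0), len(edges) - 2))
    return tuple(signature)


def oracle_l1(cases, controls, rules):
    def freqs(frame):
        counts = {}
        for _, row in frame.iterrows():
            sig = oracle_signature(row, rules)
            counts[sig] = counts.get(sig, 0) + 1
        return {sig: n / len(frame) for sig, n in counts.items()}
    fa, fb = freqs(cases), freqs(controls)
    return 0.5 * sum(abs(fa.get(sig, 0.0) - fb.get(sig, 0.0))
                     for sig in set(fa) | set(fb))


def oracle_pair_count(cases, controls, rules):
    from collections import Counter
    ca = Counter(oracle_signature(row, rules) for _, row in cases.iterrows())
    cb = Counter(oracle_signature(row, rules) for _, row in controls.iterrows())
    return sum(min(n, cb.get(sig, 0)) for sig, n in ca.items())
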
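"""Code-pattern notation: parsing, matching, registry, serialization."""

import pytest

from claimsforge.codebook import (
    CodePattern,
    CodePatternError,
    CodeSet,
    CodeSystem,
    EXCLUSION_LABELS,
    FAI_INCLUSION_LABEL,
    OPIOID_LABEL,
    COMORBIDITY_LABELS,
    PatternKind,
    builtin_registry,
    code_matches,
    codesets_from_text,
    codesets_to_text,
    exclusion_union,
    parse_pattern,
    set_matches,
)

from oracles import brute_expand, category_universe


ICD = CodeSystem.ICD9_DX


@pytest.mark.parametrize(
    "text,system,kind",
    [
        ("295.xx", ICD, PatternKind.WILDCARD),
        ("297.x", ICD, PatternKind.WILDCARD),
        ("307.8x", ICD, PatternKind.WILDCARD),
        ("v11.x", ICD, PatternKind.WILDCARD),
        ("29914", CodeSystem.CPT, PatternKind.EXACT),
        ("280808", CodeSystem.THERAPEUTIC_CLASS, PatternKind.EXACT),
        ("401.xx-405.xx", ICD, PatternKind.CATEGORY_RANGE),
        ("278.00-278.03", ICD, PatternKind.DECIMAL_RANGE),
        ("696.0-696.8", ICD, PatternKind.DECIMAL_RANGE),
        ("v85.30-v85.39", ICD, PatternKind.DECIMAL_RANGE),
        ("820", ICD, PatternKind.BARE_CATEGORY),
        ("733.42", ICD, PatternKind.EXACT),
        ("V15.82", ICD, PatternKind.EXACT),
    ],
)
def test_parse_kind_determined_by_syntax(text, system, kind):
    p = parse_pattern(text, system)
    assert p.kind is kind
    assert p.raw_text == text  # raw text round-trips byte-identically


@pytest.mark.parametrize(
    "text,system",
    [
        ("", ICD),
        ("   ", ICD),
        ("405.xx-401.xx", ICD),  # reversed category range
        ("278.03-278.00", ICD),  # reversed decimal range
        ("278.00-279.03", ICD),  # decimal range crossing categories
        ("401.xx-405.00", ICD),  # mixed range forms
        ("278.0-278.03", ICD),  # mismatched decimal widths
        ("295.xx", CodeSystem.CPT),  # wildcards are ICD-9-only notation
        ("1-2-3", ICD),
    ],
)
def test_malformed_patterns_rejected(text, system):
    with pytest.raises(CodePatternError):
        parse_pattern(text, system)


@pytest.mark.parametrize(
    "pattern,code,expected",
    [
        ("295.xx", "295.70", True),  # wildcard covers any subdivision
        ("295.xx", "296.70", False),
        ("29914", "29914", True),
        ("820", "820.21", True),  # bare category captures subdivisions
        ("820", "821.01", False),
        ("278.00-278.03", "278.8", False),  # one-digit decimal is a different code
        ("278.00-278.03", "278.00", True),
        ("278.00-278.03", "278.03", True),
        ("278.00-278.03", "278.04", False),
        ("401.xx-405.xx", "403.11", True),
        ("401.xx-405.xx", "401", True),
        ("401.xx-405.xx", "406.0", False),
        ("307.8x", "307.81", True),  # fixed fourth digit, wild fifth
        ("307.8x", "307.41", False),
        ("v15.52", "V15.52", True),  # V-codes compare case-insensitively
        ("V15.82", "v15.82", True),
        ("v85.30-v85.39", "V85.35", True),
        ("v85.30-v85.39", "V85.4", False),
    ],
)
def test_code_matching(pattern, code, expected):
    system = CodeSystem.CPT if pattern == "29914" else ICD
    assert code_matches(parse_pattern(pattern, system), code) is expected


def test_system_mismatch_is_an_error_not_false():
    p = parse_pattern("29914", CodeSystem.CPT)
    with pytest.raises(CodePatternError):
        code_matches(p, "29914", system=ICD)


def test_patterns_agree_with_bruteforce_expansion(registry):
    """Every shipped ICD-9 pattern matches exactly the codes an independent
    enumerator expands it to, over the printed-format code universe."""
    for label, cs in registry.items():
        if cs.system is not ICD:
            continue
        for p in cs.patterns:
            expected = brute_expand(p.raw_text)
            cats = {c.split(".")[0] for c in expected}
            universe = [u for cat in sorted(cats) for u in category_universe(cat)]
            got = {c for c in universe if code_matches(p, c)}
            assert got == expected, f"{label}: {p.raw_text}"


def test_range_endpoints_match_their_own_pattern(registry):
    for cs in registry.values():
        for p in cs.patterns:
            if p.kind is PatternKind.DECIMAL_RANGE:
                w = p.dec_width
                assert code_matches(p, f"{p.category}.{p.dec_lo:0{w}d}")
                assert code_matches(p, f"{p.category}.{p.dec_hi:0{w}d}")
            elif p.kind is PatternKind.CATEGORY_RANGE:
                assert code_matches(p, f"{p.cat_lo:03d}")
                assert code_matches(p, f"{p.cat_hi:03d}.99")


def test_set_matches_and_monotonicity(registry):
    excl = exclusion_union(registry)
    assert set_matches(excl, ["733.42"]) is True
    assert set_matches(excl, []) is False
    assert set_matches(registry[FAI_INCLUSION_LABEL], ["29862", "00000"]) is True

    # adding a pattern can never turn a positive set into a negative one
    grown = CodeSet(
        label="grown", system=ICD,
        patterns=excl.patterns + (parse_pattern("999", ICD),),
    )
    for code in ["733.42", "820.21", "715.15", "170.6"]:
        assert grown.matches_code(code)


def test_registry_contents(registry):
    expected = {FAI_INCLUSION_LABEL, OPIOID_LABEL} | set(EXCLUSION_LABELS) | set(
        COMORBIDITY_LABELS
    )
    assert set(registry) == expected
    assert registry["Tobacco Use"].pattern_texts() == ["V15.82"]
    assert registry[OPIOID_LABEL].pattern_texts() == ["280808", "280812"]
    assert sorted(registry[FAI_INCLUSION_LABEL].pattern_texts()) == [
        "29862", "29914", "29915", "29916",
    ]
    # the two entries printed oddly among the 327-series are kept verbatim
    sleep = registry["Sleep Disorders"].pattern_texts()
    assert "227.4" in sleep and "320.20" in sleep
    # 714.0 is deliberately present in both the exclusion screen and the
    # systemic-arthropathy comorbidity set
    assert "714.0" in registry["Other Hip Arthritic Condition"].pattern_texts()
    assert "714.0" in registry["Systemic Arthropathies"].pattern_texts()


def test_registry_override_hook():
    reg = builtin_registry(overrides={"Tobacco Use": ["305.1", "V15.82"]})
    assert reg["Tobacco Use"].pattern_texts() == ["305.1", "V15.82"]
    assert reg["Tobacco Use"].system is ICD
    with pytest.raises(KeyError):
        builtin_registry(overrides={"No Such Label": ["1"]})


def test_empty_and_mixed_system_sets_rejected():
    with pytest.raises(CodePatternError):
        CodeSet(label="empty", system=ICD, patterns=())
    with pytest.raises(CodePatternError):
        CodeSet(
            label="mixed", system=ICD,
            patterns=(parse_pattern("29914", CodeSystem.CPT),),
        )


def test_text_serialization_round_trip(registry):
    text = codesets_to_text(registry.values())
    back = codesets_from_text(text)
    assert set(back) == set(registry)
    for label in registry:
        assert back[label].pattern_texts() == registry[label].pattern_texts()
        assert back[label].system is registry[label].system


from hypothesis import given, settings, strategies as st


@settings(max_examples=150, deadline=None, derandomize=True)
@given(cat=st.integers(0, 999), a=st.integers(0, 99), b=st.integers(0, 99),
       dec=st.integers(0, 99))
def test_decimal_range_membership_property(cat, a, b, dec):
    lo, hi = sorted((a, b))
    p = parse_pattern(f"{cat:03d}.{lo:02d}-{cat:03d}.{hi:02d}", ICD)
    code = f"{cat:03d}.{dec:02d}"
    assert code_matches(p, code) is (lo <= dec <= hi)
    assert not code_matches(p, f"{cat:03d}.{dec % 10}")  # width-1 never matches


@settings(max_examples=150, deadline=None, derandomize=True)
@given(cat=st.integers(0, 999), other=st.integers(0, 999), dec=st.integers(0, 99))
def test_wildcard_matches_exactly_its_category(cat, other, dec):
    p = parse_pattern(f"{cat:03d}.xx", ICD)
    assert code_matches(p, f"{cat:03d}.{dec:02d}")
    assert code_matches(p, f"{cat:03d}.{dec % 10}")
    assert code_matches(p, f"{other:03d}.{dec:02d}") is (other == cat)
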
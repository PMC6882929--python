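"""Tour of the packaged coding vocabulary.

Prints the 26 behavior codes by category with their state/point types and
modifier vocabularies — the checklist a coder works from when annotating an
overnight recording.
"""

from opic import default_opic_ethogram

e = default_opic_ethogram()
print(f"{e.version_label}: {len(e.codes)} codes in {len(e.categories)} categories\n")
for category in e.categories:
    codes = e.codes_in_category(category)
    print(f"{category} ({len(codes)} codes)")
    for code in codes:
        mark = "S" if code.event_type.value == "STATE" else "P"
        mods = "; ".join(
            f"{m.name}: {', '.join(m.allowed_values)}" for m in code.modifier_sets
        )
        print(f"  {code.name} ({mark})" + (f"  [{mods}]" if mods else ""))
    print()

# (S) = state event, has duration; (P) = point event, a single timestamp.
# Modifiers qualify an event, e.g. whether an activity helped the child settle.
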
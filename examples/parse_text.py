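"""Parse melting-point declarations from a snippet of experimental text.

Each matched declaration is normalized to a Celsius interval; values that
look like reporting errors (implausibly high, too wide, inverted) are
flagged rather than silently dropped.
"""

from mpminer.grammar import flag_suspicious, normalize, parse_all

TEXT = """\
The crude product was recrystallized from ethanol to give white needles,
m.p. 184–186 °C. A second crop melted at mp 82-82,5 °C. The hydrochloride
salt showed melting point one hundred and five degrees Celsius, while the
free base had mpt 50 ± 1 °C. One record read mp 235-2360 (a misprint), and
a literature value was lit. m.p. 210 °C decomp.
"""

for mention in parse_all(TEXT):
    n = flag_suspicious(normalize(mention))
    flags = ",".join(sorted(r.value for r in n.suspicious_reasons)) or "-"
    print(f"{mention.raw_text!r:45s} -> [{n.low_c:7.2f}, {n.high_c:7.2f}] °C"
          f"  outcome={n.outcome.value:9s} flags={flags}")

print()
print("Each line: the raw text as matched, the normalized Celsius interval")
print("(measurement errors become ranges, decimal commas and truncated")
print("upper bounds are repaired), the melt/decompose/sublime outcome and")
print("any suspicious-value flags.")
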
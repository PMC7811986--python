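"""Physical constants used throughout the package.

The vacuum permittivity is fixed at the conventional four-digit value so that
material coefficients are reproducible to the digit across platforms; the
difference to the CODATA value is far below any tissue-property uncertainty.
"""

#: Vacuum permittivity, F/m.
EPS0 = 8.854e-12
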
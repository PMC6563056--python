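"""Physical constants and unit conventions.

Internal units: lengths in nm, energies in kJ/mol, angles in degrees stored in
the canonical range [-180, 180). NOE-facing interfaces use Angstrom.
"""

#: Boltzmann constant in kJ/(mol K)
KB = 0.0083144621

#: nm per Angstrom
NM_PER_ANGSTROM = 0.1

DEFAULT_TEMPERATURE = 300.0
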
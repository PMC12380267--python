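"""Extension nodes for the immune-regulation model.

Defines the anti-inflammatory inhibition factor 1 + a*x used to damp
neutrophil migration and pro-inflammatory cytokine production.
"""


@node(format="(1 + $1 * $2)")
def inhibition(a, x):
    """Saturating inhibition factor: 1 + a * x."""
    return 1 + a * x
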
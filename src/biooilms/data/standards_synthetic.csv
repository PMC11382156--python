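# Synthetic reconstruction of a bio-oil reference-standards table.
# The original supplementary standards list is not publicly deposited;
# this file collects the compounds named in the accompanying literature
# discussion, with their true molecular formulas. Humic acid has no
# single molecular formula and carries representative literature
# (O/C, H/C) coordinates instead.
name,formula,oc,hc,literature_class
p-coumaryl alcohol,C9H10O2,,,pyrolytic lignin
coniferyl alcohol,C10H12O3,,,pyrolytic lignin
sinapyl alcohol,C11H14O4,,,pyrolytic lignin
vanillin,C8H8O3,,,pyrolytic lignin
benzenediol,C6H6O2,,,pyrolytic lignin
p-cresol,C7H8O,,,pyrolytic lignin
guaiacol,C7H8O2,,,pyrolytic lignin
2 6-dimethoxyphenol,C8H10O3,,,pyrolytic lignin
benzyl alcohol,C7H8O,,,pyrolytic lignin
benzaldehyde,C7H6O,,,pyrolytic lignin
4-ethyl-2-methoxyphenol,C9H12O2,,,pyrolytic lignin
butanedial,C4H6O2,,,others/flavonoids
furfural,C5H4O2,,,pyrolytic humin
humic acid,,0.48,0.99,pyrolytic humin
levoglucosan,C6H10O5,,,carbohydrates
sorbitol,C6H14O6,,,carbohydrates
oleic acid,C18H34O2,,,long-chain fatty acids/alcohols
dehydroabietic acid,C20H28O2,,,terpenoids
abietic acid,C20H30O2,,,terpenoids
isopimaric acid,C20H30O2,,,terpenoids
cyclopentanone,C5H8O,,,terpenoids
eugenol,C10H12O2,,,terpenoids
thymol,C10H14O,,,terpenoids
betulinol,C30H50O2,,,terpenoids
sitosterol,C29H50O,,,long-chain fatty acids/alcohols
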
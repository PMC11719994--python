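# Functional-group SMARTS library used by ncscreen.profiling.detect_functional_groups.
#
# Exclusion rules are encoded in the patterns themselves:
#   - ether: neither oxygen neighbour may be a carbonyl carbon, so ester and
#     anhydride oxygens are not counted as ethers.
#   - ketone: requires two carbon neighbours on the carbonyl carbon, so the
#     carboxyl/ester/aldehyde carbon never matches.
#   - aldehyde: requires exactly one H on the carbonyl carbon and a carbon
#     neighbour, so formate/carboxyl carbons never match.
#   - carboxyl: carbonyl carbon bonded to a hydroxyl oxygen.
#   - aromatic: any aromatic atom.
ether: "[OD2]([#6;!$([CX3]=[OX1])])[#6;!$([CX3]=[OX1])]"
ketone: "[#6][CX3](=[OX1])[#6]"
aldehyde: "[#6][CX3H1]=[OX1]"
carboxyl: "[CX3](=[OX1])[OX2H1]"
aromatic: "[a]"
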
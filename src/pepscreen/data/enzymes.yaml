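# Bundled protease specificity library (40 enzymes, no chemical agents).
#
# Rules use Schechter-Berger position labels: P4..P1 on the amino-terminal
# side of the scissile bond, P1'..P4' on the carboxy-terminal side; cleavage
# is always at the P1-P1' bond.  A position maps to a string of allowed
# one-letter residues.  A candidate bond is cleaved when at least one entry
# of `sites` matches and no entry of `exceptions` matches; a pattern
# position that falls outside the sequence counts as a non-match.
#
# Specificities follow the PeptideCutter-style published rules, simplified
# where the literature rule is context-dependent beyond P4/P4'.  This file
# is the single source of truth for the bundled library and may be replaced
# by the user (schema: name, sites, exceptions).
version: "1.0"
enzymes:
  - name: "Arg-C Proteinase"
    sites:
      - {P1: "R"}
    exceptions:
      - {"P1'": "P"}
  - name: "Asp-N Endopeptidase"
    sites:
      - {"P1'": "D"}
  - name: "Asp-N Endopeptidase + N-terminal Glu"
    sites:
      - {"P1'": "DE"}
  - name: "Bromelain"
    sites:
      - {P1: "KAY"}
    exceptions:
      - {"P1'": "P"}
  - name: "Caspase-1"
    sites:
      - {P4: "FWYL", P2: "HAT", P1: "D"}
    exceptions:
      - {"P1'": "PEDQKR"}
  - name: "Caspase-2"
    sites:
      - {P4: "D", P3: "V", P2: "A", P1: "D"}
    exceptions:
      - {"P1'": "PEDQKR"}
  - name: "Caspase-3"
    sites:
      - {P4: "D", P3: "M", P2: "Q", P1: "D"}
    exceptions:
      - {"P1'": "PEDQKR"}
  - name: "Caspase-4"
    sites:
      - {P4: "L", P3: "E", P2: "V", P1: "D"}
    exceptions:
      - {"P1'": "PEDQKR"}
  - name: "Caspase-5"
    sites:
      - {P4: "LW", P3: "E", P2: "H", P1: "D"}
  - name: "Caspase-6"
    sites:
      - {P4: "V", P3: "E", P2: "HI", P1: "D"}
    exceptions:
      - {"P1'": "PEDQKR"}
  - name: "Caspase-7"
    sites:
      - {P4: "D", P3: "E", P2: "V", P1: "D"}
    exceptions:
      - {"P1'": "PEDQKR"}
  - name: "Caspase-8"
    sites:
      - {P4: "IL", P3: "E", P2: "T", P1: "D"}
    exceptions:
      - {"P1'": "PEDQKR"}
  - name: "Caspase-9"
    sites:
      - {P4: "L", P3: "E", P2: "H", P1: "D"}
  - name: "Caspase-10"
    sites:
      - {P4: "I", P3: "E", P2: "A", P1: "D"}
  - name: "Cathepsin B"
    sites:
      - {P2: "R", P1: "R"}
    exceptions:
      - {"P1'": "P"}
  - name: "Cathepsin G"
    sites:
      - {P1: "FWY"}
    exceptions:
      - {"P1'": "P"}
  - name: "Chymotrypsin (high specificity)"
    sites:
      - {P1: "FY"}
      - {P1: "W"}
    exceptions:
      - {P1: "FY", "P1'": "P"}
      - {P1: "W", "P1'": "MP"}
  - name: "Chymotrypsin (low specificity)"
    sites:
      - {P1: "FLY"}
      - {P1: "W"}
      - {P1: "M"}
      - {P1: "H"}
    exceptions:
      - {P1: "FLY", "P1'": "P"}
      - {P1: "W", "P1'": "MP"}
      - {P1: "M", "P1'": "PY"}
      - {P1: "H", "P1'": "DMPW"}
  - name: "Clostripain"
    sites:
      - {P1: "R"}
  - name: "Enterokinase"
    sites:
      - {P4: "DE", P3: "DE", P2: "DE", P1: "K"}
  - name: "Factor Xa"
    sites:
      - {P4: "AFGILTVM", P3: "DE", P2: "G", P1: "R"}
  - name: "Ficin"
    sites:
      - {P1: "FY"}
    exceptions:
      - {"P1'": "P"}
  - name: "Glutamyl Endopeptidase"
    sites:
      - {P1: "E"}
  - name: "Granzyme B"
    sites:
      - {P4: "I", P3: "E", P2: "P", P1: "D"}
  - name: "HRV 3C Protease"
    sites:
      - {P4: "V", P3: "L", P2: "F", P1: "Q", "P1'": "G", "P2'": "P"}
  - name: "Lys-C"
    sites:
      - {P1: "K"}
  - name: "Lys-N"
    sites:
      - {"P1'": "K"}
  - name: "Neutrophil Elastase"
    sites:
      - {P1: "AV"}
  - name: "Pancreatic Elastase"
    sites:
      - {P1: "AGSV"}
    exceptions:
      - {"P1'": "P"}
  - name: "Papain"
    sites:
      - {P2: "AVLIFWY", P1: "KR"}
    exceptions:
      - {"P1'": "P"}
  - name: "Pepsin (pH 1.3)"
    sites:
      - {P1: "FL"}
    exceptions:
      - {"P1'": "P"}
      - {P2: "P", P1: "FL"}
      - {P2: "HKR", P1: "FL"}
  - name: "Pepsin (pH >= 2)"
    sites:
      - {P1: "FLWY"}
      - {"P1'": "FLWY"}
    exceptions:
      - {"P1'": "P"}
      - {P2: "P", "P1'": "FLWY"}
      - {P1: "R"}
  - name: "Proline Endopeptidase"
    sites:
      - {P2: "HKR", P1: "P"}
    exceptions:
      - {"P1'": "P"}
  - name: "Proteinase K"
    sites:
      - {P1: "AEFILTVWY"}
  - name: "Staphylococcal Peptidase I"
    sites:
      - {P1: "E"}
    exceptions:
      - {P2: "E", P1: "E"}
  - name: "Subtilisin"
    sites:
      - {P1: "FWYLM"}
    exceptions:
      - {"P1'": "P"}
  - name: "TEV Protease"
    sites:
      - {P4: "L", P3: "Y", P2: "F", P1: "Q", "P1'": "GS"}
  - name: "Thermolysin"
    sites:
      - {"P1'": "AFILMV"}
    exceptions:
      - {P1: "DE"}
  - name: "Thrombin"
    sites:
      - {P2: "G", P1: "R", "P1'": "G"}
      - {P4: "AFGILTVM", P3: "AFGILTVW", P2: "P", P1: "R"}
    exceptions:
      - {P1: "R", "P1'": "DE"}
      - {P1: "R", "P2'": "DE"}
  - name: "Trypsin"
    sites:
      - {P1: "KR"}
    exceptions:
      - {P1: "KR", "P1'": "P"}
      - {P2: "C", P1: "K", "P1'": "D"}
      - {P2: "D", P1: "K", "P1'": "D"}
      - {P2: "C", P1: "K", "P1'": "HY"}
      - {P2: "C", P1: "R", "P1'": "K"}
      - {P2: "R", P1: "R", "P1'": "HR"}
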
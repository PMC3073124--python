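# The 43 morphological characters of the packaged arminid matrix.
# Each entry: 1-based index, short name, ordered state labels (symbol 0..k-1),
# and whether the inapplicable symbol '-' occurs in that column of the matrix.
characters:
  - {index: 1,  name: "Gill",                              states: ["present", "absent"],                                             inapplicable_allowed: false}
  - {index: 2,  name: "Gill position",                     states: ["lateral", "dorsal"],                                             inapplicable_allowed: true}
  - {index: 3,  name: "Body shape",                        states: ["oval", "wedge", "elongate"],                                     inapplicable_allowed: false}
  - {index: 4,  name: "Rhinophoral ridge",                 states: ["present", "absent"],                                             inapplicable_allowed: true}
  - {index: 5,  name: "Notal ridges",                      states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 6,  name: "Notal tubercles",                   states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 7,  name: "Notal cerata",                      states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 8,  name: "Oral structures",                   states: ["none", "tentacles", "veil"],                                     inapplicable_allowed: false}
  - {index: 9,  name: "Oral veil",                         states: ["smooth", "projections"],                                         inapplicable_allowed: true}
  - {index: 10, name: "Cephalic structure",                states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 11, name: "Caruncle",                          states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 12, name: "Rhinophoral lamellae",              states: ["horizontal", "vertical", "none"],                                inapplicable_allowed: false}
  - {index: 13, name: "Anus position",                     states: ["above pallial margin", "below pallial margin"],                  inapplicable_allowed: false}
  - {index: 14, name: "Foot tentacles",                    states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 15, name: "Anterior foot border",              states: ["not notched", "notched"],                                        inapplicable_allowed: false}
  - {index: 16, name: "Branchial lamellae",                states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 17, name: "Hyponotal lamellae",                states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 18, name: "Radula shape",                      states: ["broader than long", "slightly longer than broad", "much longer than broad"], inapplicable_allowed: false}
  - {index: 19, name: "Rachidian tooth",                   states: ["absent", "present"],                                             inapplicable_allowed: false}
  - {index: 20, name: "Rachidian tooth denticles",         states: ["none", "denticulate"],                                           inapplicable_allowed: true}
  - {index: 21, name: "Rachidian tooth denticle number",   states: ["few (five or fewer)", "many (more than five)", "state 2 (coded in the matrix but undescribed)"], inapplicable_allowed: true}
  - {index: 22, name: "Rachidian central cusp",            states: ["not projecting", "slightly projecting", "greatly projecting"],   inapplicable_allowed: true}
  - {index: 23, name: "Rachidian tooth shape",             states: ["narrow", "broad"],                                               inapplicable_allowed: true}
  - {index: 24, name: "Top of rachidian tooth",            states: ["flat or slightly indented", "elongate bases and deep notches"],  inapplicable_allowed: true}
  - {index: 25, name: "Inner lateral tooth",               states: ["smooth", "denticulate"],                                         inapplicable_allowed: true}
  - {index: 26, name: "Inner lateral tooth width",         states: ["narrow", "medium", "broad"],                                     inapplicable_allowed: true}
  - {index: 27, name: "Inner lateral tooth shape",         states: ["hammate, directed downward", "elongate, laterally directed"],    inapplicable_allowed: true}
  - {index: 28, name: "Second lateral tooth",              states: ["denticulate", "smooth"],                                         inapplicable_allowed: true}
  - {index: 29, name: "Middle lateral teeth",              states: ["denticulate", "smooth"],                                         inapplicable_allowed: true}
  - {index: 30, name: "Outer lateral teeth",               states: ["denticulate", "smooth"],                                         inapplicable_allowed: true}
  - {index: 31, name: "Jaw",                               states: ["present", "absent"],                                             inapplicable_allowed: false}
  - {index: 32, name: "Masticatory border",                states: ["distinct", "indistinct"],                                        inapplicable_allowed: true}
  - {index: 33, name: "Masticatory margin",                states: ["denticulate", "smooth"],                                         inapplicable_allowed: true}
  - {index: 34, name: "Jaw denticles",                     states: ["seven to ten rows", "three to six rows", "one to two rows"],     inapplicable_allowed: true}
  - {index: 35, name: "Denticle location",                 states: ["along entire margin", "basally", "near hinge"],                  inapplicable_allowed: true}
  - {index: 36, name: "Denticle shape",                    states: ["acutely pointed", "rounded", "multifid"],                        inapplicable_allowed: true}
  - {index: 37, name: "Reproductive system",               states: ["androdiaulic", "diaulic", "triaulic"],                           inapplicable_allowed: false}
  - {index: 38, name: "Ampulla",                           states: ["tubular", "mass"],                                               inapplicable_allowed: true}
  - {index: 39, name: "Penial sheath",                     states: ["bulbous", "narrow"],                                             inapplicable_allowed: true}
  - {index: 40, name: "Deferent duct",                     states: ["long", "short"],                                                 inapplicable_allowed: false}
  - {index: 41, name: "Bursa duct",                        states: ["distinct duct present", "bursa duct absent"],                    inapplicable_allowed: false}
  - {index: 42, name: "Vaginal duct",                      states: ["long", "short"],                                                 inapplicable_allowed: false}
  - {index: 43, name: "Vaginal width",                     states: ["uniform", "basally wider"],                                      inapplicable_allowed: false}
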
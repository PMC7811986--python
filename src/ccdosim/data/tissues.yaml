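# Bundled dielectric parameters for the phantom materials.
#
# One-term Cole-Cole models with representative low-frequency values in the
# style of the Gabriel parametrisation.  They are deliberately compact stand-ins
# for a full multi-term tissue database: sufficient for DC-1 MHz contact-current
# dosimetry on the synthetic phantom, and every entry can be overridden by a
# user-supplied table.  sigma_dc in S/m, tau in seconds.
#
# Skeletal muscle uses the longitudinal (along-fibre) conductivity; the package
# treats muscle as isotropic at that value.
# The two engineered materials are pinned by the contact model: the electrode
# bulk at 1.0 S/m and intact skin at 0.2 mS/m at ELF.

- name: muscle
  mode: cole_cole
  sigma_dc: 0.35
  eps_inf: 1.0e3
  terms:
    - {delta_eps: 9.0e6, tau: 2.0e-3, alpha: 0.10}
  note: skeletal muscle, isotropic at the longitudinal conductivity value

- name: fat
  mode: cole_cole
  sigma_dc: 0.04
  eps_inf: 1.0e2
  terms:
    - {delta_eps: 5.0e5, tau: 5.0e-3, alpha: 0.20}
  note: subcutaneous adipose tissue

- name: bone
  mode: cole_cole
  sigma_dc: 0.02
  eps_inf: 4.0e1
  terms:
    - {delta_eps: 4.0e3, tau: 1.6e-4, alpha: 0.20}
  note: cortical bone

- name: lung
  mode: cole_cole
  sigma_dc: 0.10
  eps_inf: 5.0e2
  terms:
    - {delta_eps: 4.0e6, tau: 3.0e-3, alpha: 0.10}
  note: inflated lung

- name: blood
  mode: cole_cole
  sigma_dc: 0.70
  eps_inf: 2.0e3
  terms:
    - {delta_eps: 3.0e3, tau: 1.6e-7, alpha: 0.10}
  note: whole blood (heart lumen and vessel channels)

- name: heart_muscle
  mode: cole_cole
  sigma_dc: 0.08
  eps_inf: 8.0e2
  terms:
    - {delta_eps: 8.0e6, tau: 2.5e-3, alpha: 0.15}
  note: ventricular myocardium

- name: skin
  mode: cole_cole
  sigma_dc: 2.0e-4
  eps_inf: 1.0e3
  terms:
    - {delta_eps: 4.5e4, tau: 7.96e-6, alpha: 0.10}
  note: intact dry skin, 0.2 mS/m at ELF

- name: electrode_bulk
  mode: constant
  sigma_dc: 1.0
  eps_inf: 1.0
  note: contact-electrode bulk material
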
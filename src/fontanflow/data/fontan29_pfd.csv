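case,PFD_svc_lpa__mri,PFD_svc_rpa__mri,PFD_conduit_lpa__mri,PFD_conduit_rpa__mri,PFD_total_lpa__mri,PFD_total_rpa__mri,PFD_svc_lpa__cfd,PFD_svc_rpa__cfd,PFD_conduit_lpa__cfd,PFD_conduit_rpa__cfd,PFD_total_lpa__cfd,PFD_total_rpa__cfd
case01,73.6,26.4,1.1,98.9,39.0,61.0,83.8,16.2,18.0,82.0,26.0,74.0
case02,1.1,98.9,62.8,37.2,51.7,48.3,25.0,75.0,60.7,39.3,23.6,76.4
case03,20.2,79.8,100.0,0.0,59.5,40.5,42.2,57.8,68.7,31.3,46.7,53.3
case04,88.7,11.3,36.2,63.8,43.3,56.7,74.1,25.9,30.6,69.4,61.0,39.0
case05,86.8,13.2,4.0,96.0,68.2,31.8,42.5,57.5,80.5,19.5,38.1,61.9
case06,67.6,32.4,0.0,100.0,38.6,61.4,74.0,26.0,17.6,82.4,58.3,41.7
case07,99.5,0.5,10.9,89.1,57.0,43.0,99.4,0.6,20.0,80.0,66.2,33.8
case08,78.4,21.6,6.0,94.0,57.7,42.3,63.2,36.8,53.8,46.2,40.5,59.5
case09,12.6,87.4,71.4,28.6,58.0,42.0,29.4,70.6,74.3,25.7,32.6,67.4
case10,34.6,65.4,56.8,43.2,29.7,70.3,46.2,53.8,18.3,81.7,39.3,60.7
case11,53.4,46.6,85.3,14.7,62.2,37.8,33.2,66.8,79.8,20.2,59.5,40.5
case12,3.1,96.9,72.9,27.1,38.0,62.0,16.4,83.6,51.8,48.2,35.6,64.4
case13,5.7,94.3,87.7,12.3,48.4,51.6,37.2,62.8,55.1,44.9,34.7,65.3
case14,0.4,99.6,80.9,19.1,38.8,61.2,33.9,66.1,40.4,59.6,47.2,52.8
case15,96.2,3.8,4.4,95.6,30.5,69.5,74.1,25.9,12.0,88.0,67.2,32.8
case16,16.1,83.9,18.0,82.0,14.0,86.0,0.0,100.0,20.5,79.5,17.4,82.6
case17,48.7,51.3,23.2,76.8,35.6,64.4,82.2,17.8,11.2,88.8,38.8,61.2
case18,5.4,94.6,100.0,0.0,62.1,37.9,26.7,73.3,77.9,22.1,20.0,80.0
case19,12.3,87.7,43.7,56.3,23.3,76.7,35.4,64.6,19.1,80.9,25.1,74.9
case20,60.5,39.5,51.3,48.7,21.5,78.5,42.5,57.5,4.5,95.5,37.6,62.4
case21,7.1,92.9,42.6,57.4,17.0,83.0,21.3,78.7,14.6,85.4,18.0,82.0
case22,62.5,37.5,44.9,55.1,31.8,68.2,78.7,21.3,7.4,92.6,51.7,48.3
case23,20.2,79.8,0.1,99.9,17.2,82.8,52.7,47.3,0.7,99.3,4.6,95.4
case24,4.0,96.0,95.9,4.1,49.6,50.4,18.5,81.5,69.3,30.7,43.0,57.0
case25,73.8,26.2,28.9,71.1,43.4,56.6,82.6,17.4,25.6,74.4,52.7,47.3
case26,24.6,75.4,100.0,0.0,25.8,74.2,38.8,61.2,18.0,82.0,27.5,72.5
case27,71.2,28.8,0.7,99.3,54.7,45.3,30.4,69.6,66.6,33.4,57.1,42.9
case28,6.6,93.4,100.0,0.0,56.2,43.8,6.5,93.5,89.0,11.0,64.6,35.4
case29,23.0,77.0,46.7,53.3,24.7,75.3,41.0,59.0,17.2,82.9,31.0,69.0
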
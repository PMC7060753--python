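Area,Country,RMU,Incubation.temperature,Incubation.temperature.Amplitude,Males,Females,Intersexes,Reference
Pirambu Beach,Brazil,West Atlantic,26.3,0.3,2,0,0,1
Pirambu Beach,Brazil,West Atlantic,28.5,0.2,3,0,0,1
Pirambu Beach,Brazil,West Atlantic,29.2,0.2,8,1,0,1
Pirambu Beach,Brazil,West Atlantic,29.9,0.5,7,0,0,1
Pirambu Beach,Brazil,West Atlantic,30.4,0.2,5,2,0,1
Pirambu Beach,Brazil,West Atlantic,31.2,1.9,0,1,0,1
Pirambu Beach,Brazil,West Atlantic,31.8,1.2,0,3,0,1
Pirambu Beach,Brazil,West Atlantic,32.1,0.4,0,6,0,1
Pirambu Beach,Brazil,West Atlantic,32.2,0.4,0,2,0,1
Pirambu Beach,Brazil,West Atlantic,32.4,1.9,0,1,0,1
Pirambu Beach,Brazil,West Atlantic,32.9,0.6,0,5,0,1
Pirambu Beach,Brazil,West Atlantic,33.1,0.3,0,4,0,1
Odisha,India,Northeast Indian,26.5,,3,0,0,2;3
Odisha,India,Northeast Indian,28,,8,0,0,2;3
Odisha,India,Northeast Indian,29.5,,2,3,0,2;3
Odisha,India,Northeast Indian,30,,0,4,0,2;3
Odisha,India,Northeast Indian,31,,0,2,0,2;3
Odisha,India,Northeast Indian,31.5,,0,9,0,2;3
Nancite,Costa Rica,East Pacific,25,,23,0,0,4
Nancite,Costa Rica,East Pacific,28,,30,1,3,4
Nancite,Costa Rica,East Pacific,30,,12,8,5,4
Nancite,Costa Rica,East Pacific,32,,0,23,0,4
Nancite,Costa Rica,East Pacific,27,0.5,15,0,0,5
Nancite,Costa Rica,East Pacific,29.4,0.5,23,1,0,5
Nancite,Costa Rica,East Pacific,30.4,0.5,16,3,0,5
Nancite,Costa Rica,East Pacific,32,0.5,0,19,0,5
La Escobilla,Mexico,East Pacific,27,,25,0,0,6
La Escobilla,Mexico,East Pacific,32,,0,26,0,6
La Escobilla,Mexico,East Pacific,27.5,,15,0,0,7
La Escobilla,Mexico,East Pacific,32,,0,9,0,7
Playa La Destiladeras,Mexico,East Pacific,27.61,0.79,3,0,4,8
Playa La Destiladeras,Mexico,East Pacific,32.24,0.81,0,5,6,8
Playa La Destiladeras,Mexico,East Pacific,28.62,0.86,2,0,0,8
Playa La Destiladeras,Mexico,East Pacific,32.29,1.05,0,1,1,8
El Verde Camacho,Mexico,East Pacific,24,0.1,16,0,0,9
El Verde Camacho,Mexico,East Pacific,26,0.1,24,0,0,9
El Verde Camacho,Mexico,East Pacific,28,0.1,20,0,0,9
El Verde Camacho,Mexico,East Pacific,30,0.1,15,4,0,9
El Verde Camacho,Mexico,East Pacific,32,0.1,0,20,0,9
El Verde Camacho,Mexico,East Pacific,34,0.1,0,5,0,9
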